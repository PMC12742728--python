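"""Predict one adult's weight with every evaluable equation.

Builds a single record from tape-and-caliper measurements and prints each
equation's prediction next to the measured weight. Differences of a few kg
are typical; equations using only height (KK) drift furthest.
"""

from anthroweight import EQUATION_IDS, predict_weight
from anthroweight.records import AnthropometricRecord

record = AnthropometricRecord(
    participant_id="demo",
    sex="male",
    age=30,
    weight=64.5,   # measured, for comparison only
    height=162.5,
    mac=28.6,
    ac=81.8,
    cc=34.5,
    hc=96.5,
    kh=51.5,
    sst=12,
)

print(f"measured weight: {record.weight} kg")
for eq in EQUATION_IDS:
    pred = predict_weight(record, eq)
    err = 100.0 * (pred - record.weight) / record.weight
    print(f"  {eq:>2}: {pred:6.2f} kg  ({err:+5.1f}% vs measured)")
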