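"""Core domain types: participant records and sex coding.

A record set is represented throughout the package as a :class:`pandas.DataFrame`
with the canonical columns listed in :data:`MEASUREMENT_FIELDS` plus ``id`` and
``sex``; :class:`AnthropometricRecord` is the single-participant view used by
the scalar prediction API and the CLI.

Units are fixed: all lengths and circumferences in centimetres, subscapular
skinfold thickness (``sst``) in millimetres, age in years, weight in kilograms.
Ingest rejects out-of-range values rather than converting or clamping them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Optional

__all__ = [
    "Sex",
    "sex_code",
    "parse_sex",
    "AnthropometricRecord",
    "MEASUREMENT_FIELDS",
    "FIELD_BOUNDS",
    "RecordError",
]


class RecordError(ValueError):
    """A record violates a domain invariant (bad sex label, out-of-range value)."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    def __str__(self) -> str:  # so DataFrame round-trips store plain labels
        return self.value


#: Numeric sex encoding used inside equations with a coded-sex term.
_SEX_CODES = {Sex.MALE: 1, Sex.FEMALE: 2}

#: Accepted textual/numeric aliases, matched case-insensitively at ingest.
_SEX_ALIASES = {
    "male": Sex.MALE, "m": Sex.MALE, "1": Sex.MALE,
    "female": Sex.FEMALE, "f": Sex.FEMALE, "2": Sex.FEMALE,
}

#: Measurement columns of a record set, in canonical order.
MEASUREMENT_FIELDS = (
    "age", "weight", "height", "mac", "ac", "cc", "hc", "kh", "sst",
)

#: Plausibility bounds applied at ingest (inclusive). Values outside are
#: rejected, never clamped. Overridable via the ingest schema.
FIELD_BOUNDS: Mapping[str, tuple[float, float]] = {
    "age": (18.0, 120.0),
    "weight": (20.0, 300.0),
    "height": (100.0, 250.0),
    "mac": (10.0, 60.0),
    "ac": (40.0, 200.0),
    "cc": (15.0, 70.0),
    "hc": (50.0, 200.0),
    "kh": (30.0, 80.0),
    "sst": (2.0, 60.0),
}


def parse_sex(value: object) -> Sex:
    """Normalize a sex label (``male``/``female``/``m``/``f``/``1``/``2``).

    Raises :class:`RecordError` for anything else; ingest never guesses.
    """
    if isinstance(value, Sex):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        value = str(int(value)) if float(value).is_integer() else str(value)
    token = str(value).strip().lower()
    try:
        return _SEX_ALIASES[token]
    except KeyError:
        raise RecordError(f"unrecognized sex label: {value!r}") from None


def sex_code(sex: Sex | str) -> int:
    """Return the coded-sex value used inside the equations: male=1, female=2."""
    return _SEX_CODES[parse_sex(sex)]


@dataclass(frozen=True)
class AnthropometricRecord:
    """One participant's measurements.

    Any measurement field may be ``None`` (missing); an equation is evaluable
    only when all of its required variables are present.
    """

    participant_id: str
    sex: Sex
    age: Optional[float] = None      # years
    weight: Optional[float] = None   # kg, measured actual weight
    height: Optional[float] = None   # cm
    mac: Optional[float] = None      # cm, mid-arm circumference
    ac: Optional[float] = None       # cm, abdominal circumference
    cc: Optional[float] = None       # cm, calf circumference
    hc: Optional[float] = None       # cm, hip circumference
    kh: Optional[float] = None       # cm, knee height
    sst: Optional[float] = None      # mm, subscapular skinfold thickness

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", parse_sex(self.sex))
        for name in MEASUREMENT_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if isinstance(value, float) and math.isnan(value):
                object.__setattr__(self, name, None)
                continue
            value = float(value)
            lo, hi = FIELD_BOUNDS[name]
            if not (lo <= value <= hi):
                raise RecordError(
                    f"{name}={value} outside plausible range [{lo}, {hi}] "
                    f"for participant {self.participant_id!r}"
                )
            object.__setattr__(self, name, value)

    @property
    def sex_code(self) -> int:
        return sex_code(self.sex)

    def get(self, variable: str):
        """Look up an equation variable; ``sex_code`` resolves to 1/2."""
        if variable == "sex_code":
            return self.sex_code
        return getattr(self, variable)

    def missing(self, variables) -> list[str]:
        """Return which of *variables* are absent on this record."""
        return [v for v in variables if self.get(v) is None]
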