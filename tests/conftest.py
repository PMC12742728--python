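import numpy as np
import pandas as pd
import pytest

from anthroweight import SyntheticConfig, generate_cohort
from anthroweight.records import MEASUREMENT_FIELDS


#: measurement ranges used for randomized equation-input sampling
VARIABLE_RANGES = {
    "age": (18.0, 90.0),
    "height": (130.0, 210.0),
    "mac": (15.0, 45.0),
    "ac": (50.0, 150.0),
    "cc": (20.0, 55.0),
    "hc": (60.0, 150.0),
    "kh": (35.0, 70.0),
    "sst": (3.0, 45.0),
}


def random_measurements(rng):
    """One fully-populated measurement dict drawn uniformly over ranges."""
    return {k: rng.uniform(lo, hi) for k, (lo, hi) in VARIABLE_RANGES.items()}


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(SyntheticConfig(seed=20260930))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
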