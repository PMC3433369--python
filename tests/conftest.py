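import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chdval.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """5k-subject no-CHD-history cohort generated from the UKPDS engine."""
    return generate_cohort(CohortConfig(n=5000, seed=42))


@pytest.fixture(scope="session")
def secondary_cohort():
    """2k-subject CHD-history cohort generated from the secondary equation."""
    return generate_cohort(CohortConfig(n=2000, stratum="chd_history",
                                        true_model="fram_secondary", seed=43))


def random_profiles(rng, n):
    """Random valid cohort table spanning the covariate space broadly."""
    return pd.DataFrame({
        "subject_id": np.arange(n),
        "age": rng.uniform(18, 95, n),
        "sex": rng.choice(["male", "female"], n),
        "afro_caribbean": rng.integers(0, 2, n),
        "smoker": rng.integers(0, 2, n),
        "hba1c": rng.uniform(4, 14, n),
        "sbp": rng.uniform(85, 220, n),
        "dbp": rng.uniform(45, 130, n),
        "total_cholesterol": rng.uniform(90, 360, n),
        "hdl": rng.uniform(15, 110, n),
        "diabetes_duration": rng.uniform(0, 40, n),
        "diabetes": 1,
        "chd_history": 0,
    })
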