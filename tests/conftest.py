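import numpy as np
import pandas as pd
import pytest

from tierstack import CohortSpec, generate_cohort
from tierstack.registry import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 4,000-patient, 2-year synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n_patients=4000, n_years=2, seed=42))


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """A 10,000-patient cohort for distributional checks."""
    return generate_cohort(CohortSpec(n_patients=10_000, n_years=2, seed=7))


@pytest.fixture(scope="session")
def los_design_cols() -> list:
    return FEATURE_COLUMNS + ["current_los_days"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_eligible() -> pd.DataFrame:
    """A small deterministic benefit base spanning all three predicted tiers."""
    rng = np.random.default_rng(5)
    n = 300
    tiers = rng.integers(1, 4, n)
    costs = np.round(rng.lognormal(9.0, 1.0, n), 2)
    return pd.DataFrame({"predicted_tier": tiers, "cost": costs})
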