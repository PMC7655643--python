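import numpy as np
import pandas as pd
import pytest

from liprod import default_config, generate_herd
from liprod.herd_model import FA_DESIRABLE, FA_UNDESIRABLE


@pytest.fixture(scope="session")
def study_config():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def default_herd(study_config):
    return generate_herd(study_config)


def make_complete_cohort(n: int = 10) -> pd.DataFrame:
    """Deterministic cohort of n complete records; record index n-1 is best
    on every variable (highest desirables, lowest undesirables, untreated)."""
    i = np.arange(n, dtype=float)
    df = pd.DataFrame({
        "cow_id": [f"C{k:02d}" for k in range(n)],
        "date_code": "D2",
        "farm_id": (np.arange(n) % 3) + 1,
        "breed_code": "HF",
        "yield_l_day": 10.0 + i,
        "solids_kg_day": 0.5 + 0.1 * i,
        "scc_kcells_ml": 500.0 - 40.0 * i,
        "treatments_n": np.where(i == n - 1, 0, 1),
    })
    for var in FA_DESIRABLE:
        df[var] = 1.0 + 0.1 * i
    for var in FA_UNDESIRABLE:
        df[var] = 30.0 - i
    return df


@pytest.fixture
def complete_cohort():
    return make_complete_cohort(10)
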