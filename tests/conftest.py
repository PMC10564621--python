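import numpy as np
import pandas as pd
import pytest

from scanthro import CohortConfig, SyntheticConfig, generate_cohort
from scanthro.cohort import FOOD_FLAG_COLUMNS


def make_cohort_frame(n=3, sex="male", with_scan=True, seed=0):
    """Minimal valid cohort DataFrame built by hand (no generator)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "sex": sex,
            "age": rng.integers(20, 80, n),
            "height_cm": rng.normal(175, 6, n).round(1),
            "weight_kg": rng.normal(78, 8, n).round(1),
            "rfm_pct": rng.uniform(15, 35, n).round(1),
            "vat_kg": rng.uniform(0.5, 4, n).round(2),
            "smm_kg": rng.uniform(20, 35, n).round(1),
            "education_raw": rng.integers(1, 8, n),
            "activity_raw": rng.integers(1, 6, n),
        }
    )
    for c in FOOD_FLAG_COLUMNS:
        df[c] = rng.integers(0, 2, n)
    if with_scan:
        df["waist_girth"] = rng.normal(95, 8, n).round(1)
        df["hip_girth"] = rng.normal(102, 6, n).round(1)
    return df


@pytest.fixture(scope="session")
def male_cohort():
    """One male stratum (n=200) with known sparse truth, shared across tests."""
    cfg = SyntheticConfig(sex="male", n=200, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_sex_cohort():
    cfg = CohortConfig(
        male=SyntheticConfig(sex="male", n=80),
        female=SyntheticConfig(sex="female", n=80),
        seed=7,
    )
    return generate_cohort(cfg)
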