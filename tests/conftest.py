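import numpy as np
import pandas as pd
import pytest

from sustdiet.synthetic import CohortConfig, cohort_frame, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One default-condition cohort without RR/task payloads (fast)."""
    cfg = CohortConfig(seed=7, include_rr=False, include_task_logs=False)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    return cohort_frame(small_cohort)


@pytest.fixture(scope="session")
def toy_composition():
    """Three-item composition table with easy round numbers."""
    cols = {
        "portion_g": [100.0, 50.0, 200.0],
        "energy_kcal": [200.0, 400.0, 50.0],
        "protein_g": [20.0, 10.0, 1.0],
        "iron_mg": [10.0, 2.0, 0.5],
        "zinc_mg": [5.0, 1.0, 0.2],
        "selenium_ug": [30.0, 5.0, 1.0],
        "folate_ug": [50.0, 20.0, 10.0],
        "b12_ug": [2.0, 0.0, 0.0],
        "calcium_mg": [100.0, 50.0, 10.0],
        "copper_mg": [0.5, 0.2, 0.05],
        "magnesium_mg": [100.0, 30.0, 10.0],
        "iodine_ug": [20.0, 5.0, 1.0],
        "sfa_g": [5.0, 2.0, 0.0],
        "pufa_g": [2.0, 1.0, 0.0],
        "n3_long_g": [0.5, 0.0, 0.0],
        "trans_g": [0.1, 0.0, 0.0],
        "sodium_mg": [100.0, 500.0, 5.0],
        "added_sugar_g": [0.0, 5.0, 8.0],
    }
    return pd.DataFrame(cols, index=pd.Index(["meat", "biscuit", "juice"], name="item"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
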