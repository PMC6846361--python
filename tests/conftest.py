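import numpy as np
import pandas as pd
import pytest

from gfrbench.cohort import Cohort


def make_cohort(mgfr, egfr_model=None, **overrides) -> Cohort:
    """Tiny hand-controlled cohort with defaulted demographics."""
    n = len(mgfr)
    base = {
        "patient_id": [f"T{i}" for i in range(n)],
        "center": ["Cambridge"] * n,
        "diagnosis_group": ["solid_cancer"] * n,
        "sex": ["male"] * n,
        "race_black": [False] * n,
        "age": [60.0] * n,
        "height_cm": [169.0] * n,
        "weight_kg": [74.0] * n,
        "creatinine_mgdl": [0.95] * n,
        "creatinine_date": pd.to_datetime(["2015-01-05"] * n),
        "mgfr_ml_min": list(map(float, mgfr)),
        "tracer": ["cr51_edta"] * n,
        "mgfr_date": pd.to_datetime(["2015-01-05"] * n),
    }
    base.update(overrides)
    return Cohort(records=pd.DataFrame(base))


@pytest.fixture
def toy_cohort():
    """Four patients, mGFR all 100, used with fixed eGFR vectors."""
    return make_cohort([100.0, 100.0, 100.0, 100.0])


@pytest.fixture
def random_record_frame():
    """Factory for random valid record frames of a requested size."""

    def factory(n, seed):
        rng = np.random.default_rng(seed)
        sex = rng.choice(["male", "female"], n)
        return make_cohort(
            rng.uniform(10, 200, n),
            patient_id=[f"R{i}" for i in range(n)],
            sex=list(sex),
            race_black=list(rng.random(n) < 0.05),
            age=list(rng.uniform(18, 91, n)),
            height_cm=list(rng.uniform(140, 200, n)),
            weight_kg=list(rng.uniform(40, 140, n)),
            creatinine_mgdl=list(np.exp(rng.uniform(np.log(0.25), np.log(4.4), n))),
        )

    return factory
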