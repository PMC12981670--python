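import numpy as np
import pandas as pd
import pytest

from collabsim import ModelConfig, generate_cohort
from collabsim.cohort import COHORT_COLUMNS, Cohort, CohortSpec, discharge_spec


@pytest.fixture(scope="session")
def triage_cohort():
    return generate_cohort(CohortSpec(n_patients=6000, seed=11))


@pytest.fixture(scope="session")
def discharge_cohort():
    return generate_cohort(discharge_spec(n_patients=6000, seed=12))


@pytest.fixture(scope="session")
def fast_model_config():
    """Small ensemble for unit tests that exercise the training path."""
    return ModelConfig(max_trees=150, early_stopping_rounds=15, seed=3)


def make_cohort(
    n=100,
    task="triage",
    age=40,
    esi=3,
    disposition="discharge",
    outcome=None,
    n_medications=1,
    n_chronic_conditions=1,
    chief_complaint="headache",
    seed=0,
):
    """Hand-built minimal cohort for targeted behavioral tests."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n) if outcome is None else np.asarray(outcome, int)
    n = len(y)

    def expand(v):
        return np.full(n, v) if np.isscalar(v) or isinstance(v, str) else np.asarray(v)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": expand(age),
            "sex": expand("male"),
            "race": expand("white"),
            "heart_rate": rng.normal(80, 5, n).round(),
            "resp_rate": rng.normal(16, 2, n).round(),
            "sbp": rng.normal(120, 5, n).round(),
            "dbp": rng.normal(75, 4, n).round(),
            "spo2": np.minimum(rng.normal(97, 1, n).round(), 100),
            "temperature": rng.normal(37, 0.2, n).round(1),
            "esi": expand(esi),
            "disposition": expand(disposition),
            "chief_complaint": expand(chief_complaint),
            "n_prior_ed_visits": np.zeros(n, int),
            "n_chronic_conditions": expand(n_chronic_conditions),
            "n_medications": expand(n_medications),
            "outcome": y,
        },
        columns=list(COHORT_COLUMNS),
    )
    return Cohort(task, df)
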