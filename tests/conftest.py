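import numpy as np
import pandas as pd
import pytest

from misurv import GeneratorConfig, ImputationSpec, generate_cohort, run_chained_equations


def make_cohort_df(n=6, **overrides) -> pd.DataFrame:
    """Minimal valid cohort frame; any column overridable."""
    base = {
        "id": [f"X{i}" for i in range(n)],
        "age_at_diagnosis": np.linspace(60.0, 72.0, n),
        "psa_diag": np.linspace(4.0, 18.0, n),
        "cT": ["1c"] * n,
        "cN": [0.0] * n,
        "cM": [0.0] * n,
        "first_treatment": ["radiotherapy"] * n,
        "gleason_group": ["low"] * n,
        "pT": [np.nan] * n,
        "pN": [np.nan] * n,
        "psa_post": [0.05] * n,
        "followup_days": list(range(100, 100 + 50 * n, 50)),
        "dead": [0] * n,
        "cause": [np.nan] * n,
        "sex": ["male"] * n,
        "diagnosis_year": [2005] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def masked_cohort_and_truth():
    """A small synthetic cohort with MAR-masked causes, shared across tests."""
    cfg = GeneratorConfig(n=600, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mice_result(masked_cohort_and_truth):
    cohort, _ = masked_cohort_and_truth
    spec = ImputationSpec(m=4, n_iter=4, seed=7)
    return run_chained_equations(cohort, spec)
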