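from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from traumabenefit import GeneratorConfig, generate_cohort, prepare  # noqa: E402

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_cohort_path() -> Path:
    return DATA_DIR / "toy_cohort.csv"


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data synthetic cohort, modest size, for unit tests."""
    cfg = GeneratorConfig(n=6000, seed=123, missing_rates={})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    return prepare(small_cohort.records, impute=False)


@pytest.fixture(scope="session")
def small_analysis(small_prepared) -> pd.DataFrame:
    return small_prepared.datasets[0]


def null_outcome_coefs() -> dict:
    """Generator coefficients with zero treatment effect and zero
    interactions (the null data-generating process)."""
    coefs = dict(GeneratorConfig().outcome_coefs)
    for k in list(coefs):
        if k == "treatment" or k.startswith("treat_x_"):
            coefs[k] = 0.0
    return coefs


def no_interaction_coefs() -> dict:
    """Generator coefficients with a treatment main effect but no
    interactions (constant conditional treatment log-odds)."""
    coefs = dict(GeneratorConfig().outcome_coefs)
    for k in list(coefs):
        if k.startswith("treat_x_"):
            coefs[k] = 0.0
    return coefs


def true_design_coefficients(df: pd.DataFrame, cohort, spec, names,
                             with_interactions: bool) -> np.ndarray:
    """Express the generator's true linear predictor in the fitted
    design's coordinates by exact least squares (the generating model
    lies in the design span, so the residual must vanish)."""
    from traumabenefit.model_fit import build_design
    from traumabenefit.synthetic_registry import (
        _term_values, _linear_predictor, _treatment_shift)
    cfg = cohort.config
    raw = cohort.complete_records.set_index("patient_id")
    cov = raw.loc[df["patient_id"]].reset_index()
    vals = _term_values(cov)
    base = _linear_predictor(cfg.outcome_coefs, vals, len(cov))
    shift = _treatment_shift(cfg.outcome_coefs, vals, len(cov))
    t = df["treatment"].to_numpy(dtype=float)
    true_lp = base + (t * shift if with_interactions
                      else t * float(cfg.outcome_coefs["treatment"]))
    X, nm = build_design(df, spec, with_interactions=with_interactions)
    assert nm == list(names)
    beta, res, rank, _ = np.linalg.lstsq(X, true_lp, rcond=None)
    resid = np.abs(X @ beta - true_lp).max()
    assert resid < 1e-8, f"generating model not in design span ({resid})"
    return beta
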