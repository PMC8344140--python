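"""Synthetic trauma-registry generator with known ground truth.

Emulates a national trauma-registry extract: realistic marginals for
demographics, per-region AIS scores and prehospital vitals; confounded
center-level assignment (sicker patients are preferentially taken to
Level-1 centers); a logistic in-hospital-mortality model with a small
protective Level-1 main effect plus treatment-by-severity interactions;
and missing-at-random masking of prehospital vitals at registry-typical
rates.  Because the generating mortality model lives in the same
spline/quadratic functional family that the analysis fits (linear and
quadratic terms are inside the restricted-cubic-spline / quadratic
basis span), downstream recovery and calibration tests have a
well-defined truth.

Every cohort carries a per-patient truth sidecar: mortality probability
under transport to a Level-1 center (``true_p1``), under transport to a
lower-level center (``true_p0``), and their difference, the true
individual benefit ``true_p0 - true_p1``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_prep import AIS_MERGED, RAW_COLUMNS, VITALS

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Centering constants used by the generating linear predictor (roughly the
#: cohort medians; the analysis re-estimates its own centers from data).
CENTERS = {"age": 51.0, "sbp": 137.0, "saturation": 97.0, "pulse": 90.0,
           "rr": 18.0}

#: Generating mortality coefficients, log-odds scale.  Severity terms are
#: quadratic in the ordinals (GCS deficit = 15 - GCS) and linear in the
#: centered continuous vitals.  The treatment main effect is a small
#: protective log-odds shift; interactions concentrate benefit in severe
#: head/thorax/abdomen injury and low SBP, and push toward harm at high
#: comorbidity burden.
DEFAULT_OUTCOME_COEFS = {
    "intercept": -5.00,
    "treatment": -0.06,
    "age": 0.030,
    "sex_male": 0.12,
    "cci": 0.35,
    "gcs_deficit": 0.10,
    "gcs_deficit_sq": 0.012,
    "ais_headneck": 0.20, "ais_headneck_sq": 0.040,
    "ais_thorax": 0.15, "ais_thorax_sq": 0.030,
    "ais_abdomen": 0.15, "ais_abdomen_sq": 0.030,
    "ais_extremity": 0.08, "ais_extremity_sq": 0.010,
    "ais_spine": 0.10, "ais_spine_sq": 0.015,
    "sbp": -0.012,
    "saturation": -0.05,
    "pulse": 0.006,
    "rr": 0.010,
    "treat_x_ais_headneck": -0.040,
    "treat_x_ais_thorax": -0.030,
    "treat_x_ais_abdomen": -0.025,
    "treat_x_sbp": 0.0025,
    "treat_x_cci": 0.050,
}

#: Center-level assignment: probability of direct Level-1 transport rises
#: with head injury, coma and hypotension, creating the confounding that
#: makes the unadjusted treatment association harmful while the
#: conditional effect is protective.
DEFAULT_PROPENSITY_COEFS = {
    "intercept": 0.05,
    "ais_headneck": 0.12,
    "ais_thorax": 0.05,
    "gcs_deficit": 0.04,
    "sbp": -0.004,
}

#: Registry-typical missingness rates for prehospital vitals and outcome.
DEFAULT_MISSING_RATES = {
    "saturation": 0.454,
    "rr": 0.353,
    "sbp": 0.342,
    "pulse": 0.336,
    "gcs": 0.015,
    "mortality": 0.081,
}

_PROB_EPS = 1e-6  # probabilities clipped to [eps, 1-eps]


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n: int = 10_000
    seed: int = 0
    outcome_coefs: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFS))
    propensity_coefs: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPENSITY_COEFS))
    missing_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    level3_fraction: float = 0.153   # share of non-Level-1 first transports
    transfer_fraction: float = 0.10  # comparator patients later moved to L1
    unmodeled_interaction: bool = False  # mild misspecification switch

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be a positive integer")
        for frac in (self.level3_fraction, self.transfer_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"missing rate for {var} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SyntheticCohort:
    records: pd.DataFrame      # raw registry schema (after masking)
    true_p0: np.ndarray
    true_p1: np.ndarray
    true_benefit: np.ndarray   # identically true_p0 - true_p1
    config: GeneratorConfig
    complete_records: pd.DataFrame | None = None  # pre-masking copy

    def write(self, outdir) -> None:
        """Write cohort CSV, truth sidecar CSV and config JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "cohort.csv", index=False)
        truth = pd.DataFrame({
            "patient_id": self.records["patient_id"],
            "true_p0": self.true_p0,
            "true_p1": self.true_p1,
            "true_benefit": self.true_benefit,
        })
        truth.to_csv(outdir / "truth.csv", index=False)
        (outdir / "generator_config.json").write_text(self.config.to_json())


# --------------------------------------------------------------------------
# Covariate sampling
# --------------------------------------------------------------------------

#: Per-region AIS multinomials over scores 0-5, set so the merged-region
#: shares with AIS > 2 land near registry-typical values (head/neck ~27%,
#: thorax ~23%, abdomen ~7%, spine ~7%, extremity ~11%, face ~1%).
_AIS_PROBS = {
    "ais_head":        [0.60, 0.05, 0.08, 0.14, 0.09, 0.04],
    "ais_neck":        [0.97, 0.015, 0.01, 0.004, 0.001, 0.0],
    "ais_thorax":      [0.63, 0.06, 0.08, 0.13, 0.07, 0.03],
    "ais_abdomen":     [0.80, 0.06, 0.07, 0.045, 0.02, 0.005],
    "ais_spine":       [0.82, 0.04, 0.07, 0.045, 0.02, 0.005],
    "ais_upper_ext":   [0.70, 0.12, 0.13, 0.05, 0.00, 0.00],
    "ais_lower_ext":   [0.70, 0.10, 0.12, 0.06, 0.015, 0.005],
    "ais_face":        [0.80, 0.10, 0.09, 0.008, 0.002, 0.0],
    "ais_skin":        [0.75, 0.15, 0.097, 0.002, 0.001, 0.0],
    "ais_unspecified": [0.97, 0.02, 0.009, 0.001, 0.0, 0.0],
}

#: Comorbidity-index distribution (counts 0-5); mass above 2 ~ 3-5%.
_CCI_PROBS = [0.60, 0.25, 0.10, 0.03, 0.015, 0.005]

#: High-functioning GCS distribution (applies to most patients) and the
#: depressed distribution mixed in for severe head injury.
_GCS_VALUES = np.arange(3, 16)
_GCS_BASE = np.array([0.012, 0.004, 0.004, 0.005, 0.005, 0.005, 0.007,
                      0.008, 0.010, 0.015, 0.030, 0.060, 0.835])
_GCS_SEVERE = np.array([0.40, 0.09, 0.08, 0.08, 0.07, 0.05, 0.04,
                        0.04, 0.04, 0.03, 0.03, 0.02, 0.03])


def sample_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw demographics, injuries and prehospital vitals for ``n``
    patients; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    # Age: two-component truncated normal mixture (younger injured adults
    # plus an elderly falls population), median ~51, IQR roughly [32, 68].
    comp = rng.random(n) < 0.45
    age = np.where(comp, rng.normal(32.0, 10.0, n), rng.normal(66.0, 13.0, n))
    age = np.clip(np.round(age), 18, 100).astype(int)

    sex = np.where(rng.random(n) < 0.65, "male", "female")
    cci = rng.choice(len(_CCI_PROBS), size=n, p=_CCI_PROBS)

    ais = {col: rng.choice(6, size=n, p=np.asarray(p) / np.sum(p))
           for col, p in _AIS_PROBS.items()}
    headneck = np.maximum(ais["ais_head"], ais["ais_neck"])

    # GCS: mostly 15, depressed for a share of severe head injury.
    gcs = rng.choice(_GCS_VALUES, size=n, p=_GCS_BASE / _GCS_BASE.sum())
    p_severe = np.where(headneck >= 3, 0.25 + 0.10 * (headneck - 3), 0.0)
    take = rng.random(n) < p_severe
    gcs_sev = rng.choice(_GCS_VALUES, size=n, p=_GCS_SEVERE / _GCS_SEVERE.sum())
    gcs = np.where(take, gcs_sev, gcs)

    # Vitals; SBP shifted down for torso injury and severe head injury.
    sbp = rng.normal(139.0, 25.0, n)
    sbp -= 6.0 * (ais["ais_thorax"] >= 3) + 8.0 * (ais["ais_abdomen"] >= 3)
    sbp -= 10.0 * (headneck >= 4)
    sbp = np.clip(np.round(sbp), 40, 250).astype(int)
    pulse = np.clip(np.round(rng.normal(90.0, 20.0, n)), 20, 220).astype(int)
    rr = np.clip(np.round(rng.normal(18.0, 5.0, n)), 4, 60).astype(int)
    sat = np.clip(np.round(99.0 - np.abs(rng.normal(0.0, 4.0, n))),
                  50, 100).astype(int)

    transport = rng.choice(["ambulance", "helicopter", "other", "self"],
                           size=n, p=[0.85, 0.10, 0.03, 0.02])
    novit = (rng.random(n) < np.where(gcs == 3, 0.010, 0.001)).astype(int)
    travel = np.clip(np.round(rng.lognormal(np.log(48.0), 0.45, n)),
                     5, 600).astype(int)

    df = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "age": age, "sex": sex, "comorbidity_index": cci,
        **ais,
        "gcs": gcs, "sbp": sbp, "pulse": pulse, "rr": rr, "saturation": sat,
        "transport_mode": transport,
        "no_vitals_at_arrival": novit,
        "travel_time_min": travel,
    })
    return df


# --------------------------------------------------------------------------
# Generating linear predictors (shared by outcome and propensity)
# --------------------------------------------------------------------------

def _merged_ais(cov: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "ais_headneck": np.maximum(cov["ais_head"], cov["ais_neck"]).to_numpy(),
        "ais_thorax": cov["ais_thorax"].to_numpy(),
        "ais_abdomen": cov["ais_abdomen"].to_numpy(),
        "ais_spine": cov["ais_spine"].to_numpy(),
        "ais_extremity": np.maximum(cov["ais_upper_ext"],
                                    cov["ais_lower_ext"]).to_numpy(),
    }


def _term_values(cov: pd.DataFrame) -> dict[str, np.ndarray]:
    """Named regressor values referenced by coefficient dictionaries."""
    m = _merged_ais(cov)
    gdef = 15.0 - cov["gcs"].to_numpy(float)
    vals = {
        "age": cov["age"].to_numpy(float) - CENTERS["age"],
        "sex_male": (cov["sex"].astype(str).str.lower() == "male"
                     ).to_numpy(float),
        "cci": cov["comorbidity_index"].to_numpy(float),
        "gcs_deficit": gdef,
        "gcs_deficit_sq": gdef ** 2,
        "sbp": cov["sbp"].to_numpy(float) - CENTERS["sbp"],
        "saturation": cov["saturation"].to_numpy(float) - CENTERS["saturation"],
        "pulse": cov["pulse"].to_numpy(float) - CENTERS["pulse"],
        "rr": cov["rr"].to_numpy(float) - CENTERS["rr"],
    }
    for name, arr in m.items():
        vals[name] = arr.astype(float)
        vals[name + "_sq"] = arr.astype(float) ** 2
    return vals


def _linear_predictor(coefs: dict, vals: dict[str, np.ndarray],
                      n: int) -> np.ndarray:
    lp = np.full(n, float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name in ("intercept", "treatment") or name.startswith("treat_x_"):
            continue
        if name not in vals:
            raise ConfigurationError(f"coefficient references unknown "
                                     f"variable {name!r}")
        lp += float(beta) * vals[name]
    return lp


def _treatment_shift(coefs: dict, vals: dict[str, np.ndarray],
                     n: int) -> np.ndarray:
    """Per-patient treatment log-odds shift: main effect + interactions."""
    shift = np.full(n, float(coefs.get("treatment", 0.0)))
    for name, beta in coefs.items():
        if not name.startswith("treat_x_"):
            continue
        var = name[len("treat_x_"):]
        if var not in vals:
            raise ConfigurationError(f"interaction references unknown "
                                     f"variable {var!r}")
        shift += float(beta) * vals[var]
    return shift


def _expit(x):
    with np.errstate(over="ignore"):
        return np.clip(1.0 / (1.0 + np.exp(-x)), _PROB_EPS, 1.0 - _PROB_EPS)


# --------------------------------------------------------------------------
# Assignment, outcome, missingness
# --------------------------------------------------------------------------

def assign_center_level(cov: pd.DataFrame, config: GeneratorConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli Level-1 assignment with severity-increasing propensity;
    non-Level-1 patients split into Level-2/Level-3."""
    rng = np.random.default_rng(config.seed + 1)
    vals = _term_values(cov)
    lp = _linear_predictor(config.propensity_coefs, vals, len(cov))
    treatment = (rng.random(len(cov)) < _expit(lp)).astype(int)
    level = np.ones(len(cov), dtype=int)
    ctrl = treatment == 0
    is_l3 = rng.random(len(cov)) < config.level3_fraction
    level[ctrl] = np.where(is_l3[ctrl], 3, 2)
    return treatment, level


def simulate_outcome(cov: pd.DataFrame, treatment: np.ndarray,
                     config: GeneratorConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw mortality and return (mortality, true_p0, true_p1,
    true_benefit)."""
    rng = np.random.default_rng(config.seed + 2)
    vals = _term_values(cov)
    n = len(cov)
    base = _linear_predictor(config.outcome_coefs, vals, n)
    if config.unmodeled_interaction:
        # mild misspecification: severity synergy absent from the fitted
        # additive basis
        base = base + 0.004 * vals["ais_headneck"] * vals["gcs_deficit"]
    shift = _treatment_shift(config.outcome_coefs, vals, n)
    p0 = _expit(base)
    p1 = _expit(base + shift)
    p_assigned = np.where(treatment == 1, p1, p0)
    mortality = (rng.random(n) < p_assigned).astype(int)
    return mortality, p0, p1, p0 - p1


def apply_missingness(df: pd.DataFrame, config: GeneratorConfig
                      ) -> pd.DataFrame:
    """MAR masking: per-variable missingness probability depends only on
    always-observed variables (age, head/neck AIS, center level), scaled
    so the expected marginal rate equals the configured rate.  The
    mechanism never reads the value it masks."""
    rng = np.random.default_rng(config.seed + 3)
    out = df.copy()
    headneck = np.maximum(df["ais_head"], df["ais_neck"]).to_numpy(float)
    level1 = (pd.to_numeric(df["center_level"]) == 1).to_numpy(float)
    age = df["age"].to_numpy(float)
    w = np.exp(0.20 * level1 + 0.05 * headneck + 0.002 * (age - 50.0))
    w = w / w.mean()
    for var, rate in config.missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missing rate for {var} outside [0, 1]")
        if rate == 0.0 or var not in out.columns:
            continue
        p = np.clip(rate * w, 0.0, 1.0)
        mask = rng.random(len(out)) < p
        col = out[var].astype(float)
        col[mask] = np.nan
        out[var] = col
    return out


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Sample covariates, assign centers, draw outcomes, relabel a share
    of comparator patients as transferred-in, and mask values MAR."""
    cov = sample_covariates(config)
    treatment, level = assign_center_level(cov, config)
    mortality, p0, p1, benefit = simulate_outcome(cov, treatment, config)

    rng = np.random.default_rng(config.seed + 4)
    transferred = np.zeros(len(cov), dtype=int)
    ctrl = treatment == 0
    moved = ctrl & (rng.random(len(cov)) < config.transfer_fraction)
    transferred[moved] = 1
    level = level.copy()
    level[moved] = 1  # final (recorded) center is Level-1 after transfer

    records = cov.copy()
    records["center_level"] = level
    records["transferred_in"] = transferred
    records["mortality"] = mortality
    records = records[RAW_COLUMNS]

    masked = apply_missingness(records, config)
    return SyntheticCohort(records=masked, true_p0=p0, true_p1=p1,
                           true_benefit=benefit, config=config,
                           complete_records=records)


def true_treatment(cohort: SyntheticCohort) -> np.ndarray:
    """Generating treatment indicator, recoverable from the schema:
    direct Level-1 transport = recorded Level-1 and not transferred in."""
    rec = cohort.records
    return ((pd.to_numeric(rec["center_level"]) == 1)
            & (rec["transferred_in"] == 0)).to_numpy().astype(int)
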