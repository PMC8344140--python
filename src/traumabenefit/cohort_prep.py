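"""Turn raw trauma-registry rows into the analysis cohort.

The raw schema mirrors a national trauma registry extract: one row per
patient with demographics, per-region Abbreviated Injury Scale (AIS)
scores, prehospital vital signs (single summarized values per patient),
transport mode, receiving trauma-center level, a transferred-in flag and
in-hospital mortality.  Preparation merges AIS body regions, computes the
Injury Severity Score (ISS), applies the exclusion cascade, defines the
treatment contrast, and imputes missing prehospital values under a
missing-at-random assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

#: Per-region AIS columns as they appear in the registry extract.
AIS_RAW = [
    "ais_head", "ais_neck", "ais_thorax", "ais_abdomen", "ais_spine",
    "ais_upper_ext", "ais_lower_ext", "ais_face", "ais_skin",
    "ais_unspecified",
]

#: Region-merged AIS columns used by the analysis models.
AIS_MERGED = [
    "ais_headneck", "ais_thorax", "ais_abdomen", "ais_spine",
    "ais_extremity", "ais_face", "ais_other",
]

#: The six conventional ISS body regions (spine injuries are carried as a
#: separate covariate in this schema and do not form an ISS region).
ISS_REGIONS = [
    "ais_headneck", "ais_face", "ais_thorax", "ais_abdomen",
    "ais_extremity", "ais_other",
]

#: Prehospital vitals; the only variables eligible for imputation besides
#: mortality-adjacent bookkeeping columns.
VITALS = ["gcs", "sbp", "pulse", "rr", "saturation"]

#: Full raw CSV header (one row per patient, empty field = missing).
RAW_COLUMNS = (
    ["patient_id", "age", "sex", "comorbidity_index"]
    + AIS_RAW
    + VITALS
    + ["transport_mode", "center_level", "transferred_in",
       "no_vitals_at_arrival", "travel_time_min", "mortality"]
)

CONTRASTS = ("L1_vs_L23", "L12_vs_L3")

#: Exclusion cascade, applied sequentially in this order.
EXCLUSION_RULES = [
    "transport_not_ambulance_or_helicopter",
    "age_below_18",
    "isolated_limb_injury",
    "iss_below_4",
    "no_vital_signs_at_arrival",
    "center_level_4_or_none",
    "missing_mortality",
]


class ValidationError(ValueError):
    """Raised when a raw table violates the schema contract."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a raw cohort CSV (empty fields are missing values)."""
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV lacks columns: {missing}")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# AIS merging and ISS
# --------------------------------------------------------------------------

def combine_ais_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Merge registry AIS regions into the analysis regions.

    head/neck, upper/lower extremity and skin/unspecified are each merged
    by taking the maximum (a region's severity is its worst injury);
    thorax, abdomen, spine and face pass through unchanged.
    """
    for col in AIS_RAW:
        vals = df[col].to_numpy()
        if np.any((vals < 0) | (vals > 6)):
            raise ValidationError(f"{col} outside [0, 6]")
    out = df.copy()
    out["ais_headneck"] = np.maximum(df["ais_head"], df["ais_neck"])
    out["ais_extremity"] = np.maximum(df["ais_upper_ext"], df["ais_lower_ext"])
    out["ais_other"] = np.maximum(df["ais_skin"], df["ais_unspecified"])
    return out


def compute_iss(df: pd.DataFrame) -> np.ndarray:
    """Baker ISS: sum of squares of the three highest region AIS values.

    Computed over the six ISS body regions; any region coded AIS 6
    (currently unsurvivable) sets ISS to the ceiling value 75.
    """
    ais = df[ISS_REGIONS].to_numpy(dtype=float)
    if np.any((ais < 0) | (ais > 6)):
        raise ValidationError("merged AIS outside [0, 6]")
    top3 = np.sort(ais, axis=1)[:, -3:]
    iss = (top3 ** 2).sum(axis=1).astype(int)
    iss[np.any(ais == 6, axis=1)] = 75
    return iss


# --------------------------------------------------------------------------
# Exclusion cascade
# --------------------------------------------------------------------------

def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion cascade sequentially; return survivors + counts.

    Rules, in order: non-ambulance/helicopter transport; age < 18;
    isolated limb injury (extremity AIS 1-5 with all other merged AIS 0);
    ISS < 4; no vital signs at arrival; center level 4 or undesignated;
    missing mortality.  Counts are per rule as applied sequentially
    (a patient is counted once, at the first rule that removes it).
    The cascade is idempotent: re-applying it removes nothing.
    """
    if "iss" not in df.columns:
        df = df.copy()
        df["iss"] = compute_iss(df)
    counts: dict[str, int] = {"initial": len(df)}
    kept = df

    mode = kept["transport_mode"].astype(str)
    mask = mode.isin(["ambulance", "helicopter"])
    counts[EXCLUSION_RULES[0]] = int((~mask).sum())
    kept = kept[mask]

    mask = kept["age"] >= 18
    counts[EXCLUSION_RULES[1]] = int((~mask).sum())
    kept = kept[mask]

    others = [c for c in AIS_MERGED if c != "ais_extremity"]
    isolated = (kept["ais_extremity"].between(1, 5)
                & (kept[others].to_numpy() == 0).all(axis=1))
    counts[EXCLUSION_RULES[2]] = int(isolated.sum())
    kept = kept[~isolated]

    mask = kept["iss"] >= 4
    counts[EXCLUSION_RULES[3]] = int((~mask).sum())
    kept = kept[mask]

    if "no_vitals_at_arrival" in kept.columns:
        novit = kept["no_vitals_at_arrival"].fillna(0).astype(int) == 1
    else:
        novit = pd.Series(False, index=kept.index)
    counts[EXCLUSION_RULES[4]] = int(novit.sum())
    kept = kept[~novit]

    level = pd.to_numeric(kept["center_level"], errors="coerce")
    mask = level.isin([1, 2, 3])
    counts[EXCLUSION_RULES[5]] = int((~mask).sum())
    kept = kept[mask]

    mask = kept["mortality"].notna()
    counts[EXCLUSION_RULES[6]] = int((~mask).sum())
    kept = kept[mask]

    counts["final"] = len(kept)
    return kept.copy(), counts


# --------------------------------------------------------------------------
# Treatment definition
# --------------------------------------------------------------------------

def define_treatment(df: pd.DataFrame, contrast: str) -> np.ndarray:
    """Treatment indicator by first transport destination.

    ``L1_vs_L23``: treated iff directly transported to a Level-1 center.
    ``L12_vs_L3``: treated iff directly transported to Level-1 or Level-2.
    Transferred-in patients are classified as comparator under both
    contrasts: their recorded center is not their first destination, and
    the first facility's level is not part of the schema.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    level = pd.to_numeric(df["center_level"], errors="coerce")
    if not level.isin([1, 2, 3]).all():
        raise RuntimeError(
            "level 4/undesignated records must be excluded before "
            "treatment definition")
    transferred = df["transferred_in"].fillna(0).astype(int).to_numpy() == 1
    if contrast == "L1_vs_L23":
        direct = level.to_numpy() == 1
    else:
        direct = level.to_numpy() <= 2
    return (direct & ~transferred).astype(int)


# --------------------------------------------------------------------------
# Imputation
# --------------------------------------------------------------------------

class ImputationError(RuntimeError):
    pass


@dataclass
class _PMMModel:
    variable: str
    beta: np.ndarray
    donors_pred: np.ndarray   # sorted
    donors_val: np.ndarray    # aligned with donors_pred


def _sex_male(df: pd.DataFrame) -> np.ndarray:
    if "sex_male" in df.columns:
        return df["sex_male"].astype(float).to_numpy()
    s = df["sex"]
    if s.dtype == object:
        return (s.astype(str).str.lower() == "male").astype(float).to_numpy()
    return s.astype(float).to_numpy()


def _imputation_predictors(df: pd.DataFrame) -> np.ndarray:
    """Always-complete predictor matrix for the imputation models.

    Includes treatment and outcome (both already defined and never
    imputed), following standard advice that the analysis model's
    variables belong in the imputation model.
    """
    level = pd.to_numeric(df["center_level"], errors="coerce").to_numpy(float)
    cols = [
        np.ones(len(df)),
        df["age"].to_numpy(float),
        _sex_male(df),
        df["comorbidity_index"].to_numpy(float),
        (level == 1).astype(float),
        (level == 2).astype(float),
        df["treatment"].to_numpy(float),
        df["mortality"].to_numpy(float),
    ]
    cols += [df[c].to_numpy(float) for c in AIS_MERGED]
    return np.column_stack(cols)


def impute_missing(df: pd.DataFrame, m: int = 1, seed: int = 0,
                   n_donors: int = 5) -> list[pd.DataFrame]:
    """Predictive-mean-matching imputation of missing prehospital vitals.

    Each variable with missing entries gets a linear model on the
    always-observed covariates (plus treatment and outcome); every missing
    entry is filled with the observed value of one of the ``n_donors``
    donors closest in predicted mean (drawn at random, seeded).  Returns
    ``m`` completed copies; observed cells, treatment and outcome are
    never altered.  A variable over 90% missing aborts with a diagnostic.
    """
    if "treatment" not in df.columns or df["mortality"].isna().any():
        raise ImputationError(
            "treatment and complete mortality must be defined before "
            "imputation")
    to_impute = [v for v in VITALS if v in df.columns and df[v].isna().any()]
    if not to_impute:
        return [df.copy() for _ in range(m)]

    X = _imputation_predictors(df)
    models: list[_PMMModel] = []
    for v in to_impute:
        vals = df[v].to_numpy(float)
        obs = ~np.isnan(vals)
        frac_missing = 1.0 - obs.mean()
        if frac_missing > 0.90:
            raise ImputationError(
                f"{v} is {frac_missing:.1%} missing; refusing to impute")
        beta, *_ = np.linalg.lstsq(X[obs], vals[obs], rcond=None)
        pred_obs = X[obs] @ beta
        order = np.argsort(pred_obs, kind="stable")
        models.append(_PMMModel(v, beta, pred_obs[order], vals[obs][order]))

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        comp = df.copy()
        for mod in models:
            vals = comp[mod.variable].to_numpy(float)
            miss = np.isnan(vals)
            pred_miss = X[miss] @ mod.beta
            filled = _pmm_draw(mod.donors_pred, mod.donors_val, pred_miss,
                               n_donors, rng)
            vals[miss] = filled
            comp[mod.variable] = vals
        out.append(comp)
    return out


def _pmm_draw(donors_pred: np.ndarray, donors_val: np.ndarray,
              pred: np.ndarray, k: int, rng: np.random.Generator
              ) -> np.ndarray:
    """For each prediction, draw one of the k nearest donors by predicted
    mean.  donors_pred must be sorted ascending."""
    nd = len(donors_pred)
    k = min(k, nd)
    idx = np.searchsorted(donors_pred, pred)
    # candidate window of 2k donors straddling the insertion point
    offs = np.arange(-k, k)
    cand = np.clip(idx[:, None] + offs[None, :], 0, nd - 1)
    dist = np.abs(donors_pred[cand] - pred[:, None])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=len(pred))
    chosen = np.take_along_axis(cand, np.take_along_axis(
        nearest, pick[:, None], axis=1), axis=1)[:, 0]
    return donors_val[chosen]


def complete_case(df: pd.DataFrame) -> pd.DataFrame:
    """Complete-case alternative to imputation (drop rows with any
    missing vital)."""
    mask = df[VITALS].notna().all(axis=1)
    return df[mask].copy()


# --------------------------------------------------------------------------
# End-to-end preparation
# --------------------------------------------------------------------------

@dataclass
class PreparedCohort:
    """Exclusion-filtered, treatment-defined, completed analysis data."""
    datasets: list[pd.DataFrame]      # m completed copies
    exclusion_counts: dict = field(default_factory=dict)
    contrast: str = "L1_vs_L23"


ANALYSIS_COLUMNS = (
    ["patient_id", "age", "sex_male", "comorbidity_index"]
    + AIS_MERGED + VITALS
    + ["iss", "treatment", "center_level", "mortality"]
)


def prepare(df: pd.DataFrame, contrast: str = "L1_vs_L23", m: int = 1,
            seed: int = 0, impute: bool = True) -> PreparedCohort:
    """Full preparation pipeline: merge AIS, ISS, exclusions, treatment,
    imputation (or complete case)."""
    merged = combine_ais_regions(df)
    merged["iss"] = compute_iss(merged)
    kept, counts = apply_exclusions(merged)
    kept["mortality"] = kept["mortality"].astype(int)
    kept["treatment"] = define_treatment(kept, contrast)
    kept["sex_male"] = _sex_male(kept)
    if impute:
        completed = impute_missing(kept, m=m, seed=seed)
    else:
        completed = [complete_case(kept)]
    datasets = [c[ANALYSIS_COLUMNS].reset_index(drop=True) for c in completed]
    return PreparedCohort(datasets=datasets, exclusion_counts=counts,
                          contrast=contrast)
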