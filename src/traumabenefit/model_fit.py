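"""Design construction and (penalized) logistic model fitting.

The mortality model is a logistic regression with restricted cubic
splines for the continuous prehospital variables (age, saturation,
pulse, SBP, respiration rate), quadratic polynomials (x + x^2) for the
ordinal severity scores (GCS and the merged AIS regions), linear terms
for sex and comorbidity index, a treatment indicator, and optionally
treatment interactions with AIS head/neck, AIS thorax, AIS abdomen,
centered SBP and centered comorbidity index.  Interactions are fitted
under a ridge penalty (penalized maximum likelihood) to avoid
overfitting the subtle effect modification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS_SPLINE_VARS = ["age", "saturation", "pulse", "sbp", "rr"]
ORDINAL_QUAD_VARS = ["gcs", "ais_headneck", "ais_thorax", "ais_abdomen",
                     "ais_extremity", "ais_spine"]
LINEAR_VARS = ["sex_male", "comorbidity_index"]
INTERACTION_VARS = ["ais_headneck", "ais_thorax", "ais_abdomen", "sbp",
                    "comorbidity_index"]
#: Continuous interaction variables are centered at their training mean so
#: the treatment main effect stays interpretable; ordinal AIS interactions
#: enter raw.
CENTERED_INTERACTION_VARS = ["sbp", "comorbidity_index"]

DEFAULT_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


class SeparationError(RuntimeError):
    """ML estimates diverging (complete or quasi-separation)."""


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Spline and polynomial bases
# --------------------------------------------------------------------------

@dataclass
class SplineSpec:
    """Restricted cubic spline for one variable (Harrell construction,
    normalized by the squared boundary-knot span)."""
    variable: str
    knots: np.ndarray
    train_min: float = float("-inf")
    train_max: float = float("inf")

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if len(np.unique(self.knots)) < 3:
            raise ValueError(
                f"{self.variable}: need >= 3 distinct knots, got "
                f"{self.knots!r}")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError(f"{self.variable}: knots must be strictly "
                             "increasing")

    @classmethod
    def from_quantiles(cls, variable: str, x: np.ndarray,
                       quantiles=DEFAULT_KNOT_QUANTILES) -> "SplineSpec":
        x = np.asarray(x, float)
        knots = np.unique(np.quantile(x, quantiles))
        return cls(variable, knots, float(x.min()), float(x.max()))


def rcs_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Restricted cubic spline basis: x plus k-2 nonlinear columns.

    With knots t_1 < ... < t_k the j-th nonlinear column is

        [ (x-t_j)_+^3
          - (x-t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
          + (x-t_k)_+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2

    which makes the fitted function linear beyond the boundary knots and
    puts the nonlinear columns on roughly the scale of x.
    """
    x = np.asarray(x, dtype=float)
    t = spec.knots
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (_pos(x - t[j]) ** 3
                - _pos(x - t[k - 2]) ** 3 * (t[-1] - t[j]) / (t[-1] - t[k - 2])
                + _pos(x - t[-1]) ** 3 * (t[k - 2] - t[j]) / (t[-1] - t[k - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def _pos(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0)


def poly2_basis(x: np.ndarray) -> np.ndarray:
    """Quadratic polynomial expansion (x, x^2) for ordinal scores."""
    x = np.asarray(x, dtype=float)
    return np.column_stack([x, x ** 2])


# --------------------------------------------------------------------------
# Design specification
# --------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Frozen description of the design: spline knots, centering
    constants, term lists.  Built once from training data so that
    prediction (including counterfactual prediction) reuses the
    training-time knots and centers."""
    splines: dict = field(default_factory=dict)   # var -> SplineSpec
    quad_vars: list = field(default_factory=lambda: list(ORDINAL_QUAD_VARS))
    linear_vars: list = field(default_factory=lambda: list(LINEAR_VARS))
    interaction_vars: list = field(
        default_factory=lambda: list(INTERACTION_VARS))
    centers: dict = field(default_factory=dict)   # var -> training mean

    @classmethod
    def from_training(cls, df: pd.DataFrame,
                      knot_quantiles=DEFAULT_KNOT_QUANTILES) -> "DesignSpec":
        splines = {v: SplineSpec.from_quantiles(v, df[v].to_numpy(),
                                                knot_quantiles)
                   for v in CONTINUOUS_SPLINE_VARS}
        centers = {v: float(df[v].mean()) for v in CENTERED_INTERACTION_VARS}
        return cls(splines=splines, centers=centers)

    def to_dict(self) -> dict:
        return {
            "splines": {v: {"knots": list(s.knots),
                            "train_min": s.train_min,
                            "train_max": s.train_max}
                        for v, s in self.splines.items()},
            "quad_vars": self.quad_vars,
            "linear_vars": self.linear_vars,
            "interaction_vars": self.interaction_vars,
            "centers": self.centers,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            splines={v: SplineSpec(v, np.asarray(s["knots"]),
                                   s["train_min"], s["train_max"])
                     for v, s in d["splines"].items()},
            quad_vars=list(d["quad_vars"]),
            linear_vars=list(d["linear_vars"]),
            interaction_vars=list(d["interaction_vars"]),
            centers=dict(d["centers"]),
        )


def build_design(df: pd.DataFrame, spec: DesignSpec,
                 with_interactions: bool = False,
                 treatment_override: int | None = None,
                 include_treatment: bool = True
                 ) -> tuple[np.ndarray, list[str]]:
    """Assemble the named design matrix (intercept first).

    ``treatment_override`` substitutes 0 or 1 for every patient (the
    interaction columns are recomputed accordingly) while all other
    columns keep their observed values — the mechanism behind
    counterfactual prediction.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    for v in CONTINUOUS_SPLINE_VARS:
        if v not in spec.splines:
            continue
        basis = rcs_basis(_col(df, v), spec.splines[v])
        cols.append(basis)
        names += [v] + [f"{v}_s{j + 1}" for j in range(basis.shape[1] - 1)]
    for v in spec.quad_vars:
        cols.append(poly2_basis(_col(df, v)))
        names += [v, f"{v}_sq"]
    for v in spec.linear_vars:
        cols.append(_col(df, v)[:, None])
        names.append(v)

    if include_treatment:
        if treatment_override is None:
            treat = _col(df, "treatment")
        else:
            treat = np.full(n, float(treatment_override))
        cols.append(treat[:, None])
        names.append("treatment")
        if with_interactions:
            for v in spec.interaction_vars:
                x = _col(df, v)
                if v in spec.centers:
                    x = x - spec.centers[v]
                cols.append((treat * x)[:, None])
                names.append(f"treatment_x_{v}")

    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute "
                         "or drop incomplete records first")
    return X, names


def _col(df: pd.DataFrame, v: str) -> np.ndarray:
    if v not in df.columns:
        raise KeyError(f"unknown design variable {v!r}")
    return df[v].to_numpy(dtype=float)


def interaction_mask(names: list[str]) -> np.ndarray:
    """Penalty mask selecting the treatment-interaction columns."""
    return np.array([n.startswith("treatment_x_") for n in names])


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    lam: float = 0.0
    penalized_mask: np.ndarray | None = None
    spec: DesignSpec | None = None
    with_interactions: bool = False
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    ll_path: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.beta[self.names.index(term)])

    def se(self, term: str) -> float:
        i = self.names.index(term)
        return float(np.sqrt(self.cov[i, i]))

    def to_json(self) -> str:
        return json.dumps({
            "names": self.names,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "lam": self.lam,
            "penalized_mask": (self.penalized_mask.tolist()
                               if self.penalized_mask is not None else None),
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "with_interactions": self.with_interactions,
            "loglik": self.loglik,
            "converged": self.converged,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelFit":
        d = json.loads(text)
        return cls(
            beta=np.asarray(d["beta"]),
            cov=np.asarray(d["cov"]),
            names=list(d["names"]),
            lam=float(d["lam"]),
            penalized_mask=(np.asarray(d["penalized_mask"], dtype=bool)
                            if d["penalized_mask"] is not None else None),
            spec=(DesignSpec.from_dict(d["spec"])
                  if d["spec"] is not None else None),
            with_interactions=bool(d["with_interactions"]),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
        )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: -log(1+exp(-eta)) for y=1, -log(1+exp(eta)) y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta))))


def fit_logistic_penalized(X: np.ndarray, y: np.ndarray, lam: float = 0.0,
                           mask: np.ndarray | None = None,
                           names: list[str] | None = None,
                           max_iter: int = 100, tol_ll: float = 1e-10,
                           tol_grad: float = 1e-8) -> ModelFit:
    """Penalized-ML logistic regression by Newton/IRLS with step-halving.

    Maximizes loglik(beta) - (lam/2) * sum_{j in mask} beta_j^2.  The
    covariance is the inverse penalized observed information.  With
    lam=0 (or an empty mask) this is the ordinary ML fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if mask is None:
        mask = np.zeros(p, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    D = np.zeros(p)
    D[mask] = lam

    beta = np.zeros(p)
    # start the intercept at the empirical logit (column 0 is intercept
    # by convention when it is constant)
    if np.allclose(X[:, 0], 1.0):
        pbar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
        beta[0] = np.log(pbar / (1 - pbar))

    eta = X @ beta
    pll = _bernoulli_loglik(y, eta) - 0.5 * np.sum(D * beta ** 2)
    ll_path = [pll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - D * beta
        if np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
        H = X.T @ (X * w[:, None])
        H[np.diag_indices_from(H)] += D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}")
        # step-halving keeps the penalized log-likelihood non-decreasing
        new_pll, alpha = -np.inf, 1.0
        for _ in range(40):
            cand = beta + alpha * step
            eta_c = X @ cand
            new_pll = (_bernoulli_loglik(y, eta_c)
                       - 0.5 * np.sum(D * cand ** 2))
            if new_pll >= pll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        eta = X @ beta
        rel = abs(new_pll - pll) / (abs(pll) + 1e-12)
        pll = new_pll
        ll_path.append(pll)
        if rel < tol_ll:
            converged = True
            break

    if np.max(np.abs(beta[~mask] if mask.any() else beta)) > 30.0 and lam == 0:
        raise SeparationError(
            "coefficients diverging; data may be separated — refit with a "
            "ridge penalty (fit_logistic_penalized with lam > 0)")
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(last penalized loglik {pll:.6f})")

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    H[np.diag_indices_from(H)] += D
    cov = np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)
    return ModelFit(beta=beta, cov=cov, names=list(names), lam=float(lam),
                    penalized_mask=mask, loglik=_bernoulli_loglik(y, eta),
                    n_iter=it, converged=True, ll_path=ll_path)


def fit_logistic_ml(X: np.ndarray, y: np.ndarray,
                    names: list[str] | None = None, **kw) -> ModelFit:
    """Ordinary maximum-likelihood logistic regression (IRLS)."""
    return fit_logistic_penalized(X, y, lam=0.0, mask=None, names=names, **kw)


# --------------------------------------------------------------------------
# Penalty selection
# --------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0,
                       256.0)


def select_penalty(X: np.ndarray, y: np.ndarray, mask: np.ndarray,
                   grid=DEFAULT_LAMBDA_GRID, folds: int = 10,
                   seed: int = 0) -> float:
    """Choose the ridge weight by k-fold cross-validated log-likelihood
    (folds stratified by outcome, seeded); ties go to the smaller lam."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty penalty grid")
    if len(grid) == 1:
        return float(grid[0])
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    scores = []
    for lam in grid:
        total = 0.0
        for f in range(folds):
            tr, te = fold_id != f, fold_id == f
            fit = fit_logistic_penalized(X[tr], y[tr], lam=lam, mask=mask)
            total += _bernoulli_loglik(y[te], X[te] @ fit.beta)
        scores.append(total)
    scores = np.asarray(scores)
    best = scores.max()
    # smaller lam wins ties (to numerical precision)
    for lam, s in sorted(zip(grid, scores)):
        if s >= best - 1e-9 * abs(best):
            return float(lam)
    return float(grid[int(np.argmax(scores))])


# --------------------------------------------------------------------------
# Effect reporting
# --------------------------------------------------------------------------

def extract_or(fit: ModelFit, term: str) -> dict:
    """Odds ratio with 95% Wald CI for a single coefficient."""
    b, s = fit.coef(term), fit.se(term)
    return {"term": term, "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - 1.96 * s)),
            "ci_high": float(np.exp(b + 1.96 * s)),
            "log_or": b, "se": s}


def contrast_or(fit: ModelFit, contrast: np.ndarray) -> dict:
    """Odds ratio for an arbitrary coefficient contrast c'beta."""
    c = np.asarray(contrast, dtype=float)
    b = float(c @ fit.beta)
    s = float(np.sqrt(c @ fit.cov @ c))
    return {"or": float(np.exp(b)), "ci_low": float(np.exp(b - 1.96 * s)),
            "ci_high": float(np.exp(b + 1.96 * s)), "log_or": b, "se": s}


def percentile_or(fit: ModelFit, variable: str, df: pd.DataFrame,
                  upper: float = 0.75, lower: float = 0.50) -> dict:
    """Percentile-contrast odds ratio for a spline or quadratic term
    (e.g. 75th percentile versus median of the training distribution)."""
    x = df[variable].to_numpy(dtype=float)
    q_hi, q_lo = np.quantile(x, upper), np.quantile(x, lower)
    c = np.zeros(len(fit.names))
    if fit.spec is not None and variable in fit.spec.splines:
        basis_hi = rcs_basis(np.array([q_hi]), fit.spec.splines[variable])[0]
        basis_lo = rcs_basis(np.array([q_lo]), fit.spec.splines[variable])[0]
        names = [variable] + [f"{variable}_s{j + 1}"
                              for j in range(len(basis_hi) - 1)]
        for nm, hi, lo in zip(names, basis_hi, basis_lo):
            c[fit.names.index(nm)] = hi - lo
    elif f"{variable}_sq" in fit.names:
        c[fit.names.index(variable)] = q_hi - q_lo
        c[fit.names.index(f"{variable}_sq")] = q_hi ** 2 - q_lo ** 2
    elif variable in fit.names:
        c[fit.names.index(variable)] = q_hi - q_lo
    else:
        raise KeyError(f"unknown term {variable!r}")
    out = contrast_or(fit, c)
    out.update({"term": variable, "q_upper": float(q_hi),
                "q_lower": float(q_lo)})
    return out


# --------------------------------------------------------------------------
# Multiple-imputation pooling (Rubin's rules)
# --------------------------------------------------------------------------

def pool_fits(fits: list[ModelFit]) -> ModelFit:
    """Pool coefficients and covariance across imputed datasets:
    within-imputation covariance plus (1 + 1/m) between-imputation
    coefficient covariance."""
    if len(fits) == 1:
        return fits[0]
    m = len(fits)
    betas = np.stack([f.beta for f in fits])
    beta = betas.mean(axis=0)
    within = np.mean([f.cov for f in fits], axis=0)
    dev = betas - beta
    between = dev.T @ dev / (m - 1)
    cov = within + (1 + 1 / m) * between
    f0 = fits[0]
    return ModelFit(beta=beta, cov=cov, names=f0.names, lam=f0.lam,
                    penalized_mask=f0.penalized_mask, spec=f0.spec,
                    with_interactions=f0.with_interactions,
                    loglik=float(np.mean([f.loglik for f in fits])),
                    converged=all(f.converged for f in fits))


# --------------------------------------------------------------------------
# Convenience: fit the three study models on a prepared dataset
# --------------------------------------------------------------------------

def fit_unadjusted(df: pd.DataFrame) -> ModelFit:
    X = np.column_stack([np.ones(len(df)),
                         df["treatment"].to_numpy(float)])
    return fit_logistic_ml(X, df["mortality"].to_numpy(float),
                           names=["intercept", "treatment"])


def fit_adjusted(df: pd.DataFrame, spec: DesignSpec | None = None
                 ) -> ModelFit:
    spec = spec or DesignSpec.from_training(df)
    X, names = build_design(df, spec, with_interactions=False)
    fit = fit_logistic_ml(X, df["mortality"].to_numpy(float), names=names)
    fit.spec = spec
    return fit


def fit_interactions(df: pd.DataFrame, lam: float | str = 4.0,
                     spec: DesignSpec | None = None, seed: int = 0,
                     grid=DEFAULT_LAMBDA_GRID, folds: int = 10) -> ModelFit:
    """Penalized interaction model; ``lam='auto'`` selects the ridge
    weight by cross-validation."""
    spec = spec or DesignSpec.from_training(df)
    X, names = build_design(df, spec, with_interactions=True)
    y = df["mortality"].to_numpy(float)
    mask = interaction_mask(names)
    if lam == "auto":
        lam = select_penalty(X, y, mask, grid=grid, folds=folds, seed=seed)
    fit = fit_logistic_penalized(X, y, lam=float(lam), mask=mask, names=names)
    fit.spec = spec
    fit.with_interactions = True
    return fit
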