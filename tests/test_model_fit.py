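"""Spline/quadratic bases, IRLS fits, penalization, effect reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import statsmodels.api as sm

from traumabenefit import (
    SplineSpec, DesignSpec, rcs_basis, poly2_basis, build_design,
    fit_logistic_ml, fit_logistic_penalized, select_penalty, extract_or,
    percentile_or, pool_fits, fit_adjusted, fit_interactions,
)
from traumabenefit.model_fit import SeparationError, interaction_mask, ModelFit


def _truncated_power_oracle(x, knots):
    """Literal evaluation of the restricted-cubic truncated-power
    formula, written independently of the implementation."""
    t = np.asarray(knots, float)
    k = len(t)
    norm = (t[k - 1] - t[0]) ** 2
    def plus3(u):
        return np.where(u > 0, u, 0.0) ** 3
    cols = [np.asarray(x, float)]
    for j in range(k - 2):
        term = (plus3(x - t[j])
                - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


class TestSplineBasis:
    knots = np.array([20.0, 40.0, 60.0, 90.0])

    def test_matches_independent_formula(self):
        x = np.linspace(10, 100, 100)
        spec = SplineSpec("age", self.knots)
        np.testing.assert_allclose(rcs_basis(x, spec),
                                   _truncated_power_oracle(x, self.knots),
                                   rtol=0, atol=1e-10)

    def test_nonlinear_columns_vanish_below_first_knot(self):
        x = np.linspace(0, 20, 25)
        basis = rcs_basis(x, SplineSpec("age", self.knots))
        np.testing.assert_allclose(basis[:, 1:], 0.0, atol=0)

    def test_linear_beyond_boundary_knots(self):
        """Second derivative of any basis combination is numerically zero
        outside the boundary knots (linear-tail constraint)."""
        spec = SplineSpec("age", self.knots)
        rng = np.random.default_rng(0)
        coef = rng.normal(size=3)
        h = 0.5
        for x0 in [95.0, 120.0, 5.0, 15.0]:
            pts = np.array([x0 - h, x0, x0 + h])
            f = rcs_basis(pts, spec) @ coef
            second = (f[0] - 2 * f[1] + f[2]) / h ** 2
            assert abs(second) < 1e-6

    def test_continuity_of_value_and_derivatives_at_interior_knots(self):
        spec = SplineSpec("age", self.knots)
        rng = np.random.default_rng(1)
        coef = rng.normal(size=3)
        eps = 1e-5
        for t in self.knots[1:-1]:
            pts = np.array([t - 2 * eps, t - eps, t, t + eps, t + 2 * eps])
            f = rcs_basis(pts, spec) @ coef
            d_left = (f[2] - f[0]) / (2 * eps)
            d_right = (f[4] - f[2]) / (2 * eps)
            assert abs(d_left - d_right) < 1e-3
            s_left = (f[0] - 2 * f[1] + f[2]) / eps ** 2
            s_right = (f[2] - 2 * f[3] + f[4]) / eps ** 2
            assert abs(s_left - s_right) < 1e-2

    def test_too_few_distinct_knots_rejected(self):
        with pytest.raises(ValueError):
            SplineSpec("x", [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            SplineSpec("x", [1.0, 2.0])


@given(st.integers(0, 15))
def test_poly2_is_value_and_square(v):
    np.testing.assert_array_equal(poly2_basis(np.array([v])),
                                  [[v, v * v]])


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------

class TestDesign:
    def test_override_zero_blanks_treatment_and_interactions(
            self, small_analysis):
        spec = DesignSpec.from_training(small_analysis)
        X, names = build_design(small_analysis, spec, with_interactions=True,
                                treatment_override=0)
        for i, nm in enumerate(names):
            if nm == "treatment" or nm.startswith("treatment_x_"):
                assert np.all(X[:, i] == 0.0)

    def test_no_interactions_equals_adjusted_columns(self, small_analysis):
        spec = DesignSpec.from_training(small_analysis)
        _, n_adj = build_design(small_analysis, spec, with_interactions=False)
        _, n_int = build_design(small_analysis, spec, with_interactions=True)
        assert n_int[:len(n_adj)] == n_adj
        assert all(nm.startswith("treatment_x_") for nm in n_int[len(n_adj):])

    def test_centered_interaction_column_has_mean_zero(self, small_analysis):
        spec = DesignSpec.from_training(small_analysis)
        X, names = build_design(small_analysis, spec, with_interactions=True,
                                treatment_override=1)
        j = names.index("treatment_x_sbp")
        assert abs(X[:, j].mean()) < 1e-9

    def test_missing_values_rejected(self, small_analysis):
        df = small_analysis.copy()
        df.loc[df.index[0], "sbp"] = np.nan
        spec = DesignSpec.from_training(small_analysis)
        with pytest.raises(ValueError):
            build_design(df, spec)


# --------------------------------------------------------------------------
# ML fitting
# --------------------------------------------------------------------------

def _random_dataset(seed, n=500, p=8):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n),
                         rng.normal(size=(n, p - 1))])
    beta = rng.normal(scale=0.5, size=p)
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    return X, y


def test_intercept_only_recovers_logit_prevalence():
    y = np.r_[np.ones(30), np.zeros(70)]
    fit = fit_logistic_ml(np.ones((100, 1)), y)
    assert fit.beta[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)


def test_single_binary_covariate_closed_form():
    y = np.r_[np.ones(10), np.zeros(90), np.ones(5), np.zeros(95)]
    x = np.r_[np.ones(100), np.zeros(100)]
    fit = fit_logistic_ml(np.column_stack([np.ones(200), x]), y)
    assert fit.beta[1] == pytest.approx(np.log((10 * 95) / (90 * 5)),
                                        abs=1e-8)


def test_matches_statsmodels_on_random_data():
    X, y = _random_dataset(7)
    fit = fit_logistic_ml(X, y)
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(fit.beta, ref.params, atol=1e-8)
    np.testing.assert_allclose(fit.cov, ref.cov_params(), atol=1e-8)


def test_loglik_nondecreasing_over_iterations():
    X, y = _random_dataset(11)
    fit = fit_logistic_ml(X, y)
    diffs = np.diff(fit.ll_path)
    assert np.all(diffs >= -1e-9)


def test_separation_raises_with_penalty_advice():
    x = np.r_[np.linspace(-2, -0.1, 30), np.linspace(0.1, 2, 30)]
    y = (x > 0).astype(float)
    X = np.column_stack([np.ones(60), x])
    with pytest.raises(SeparationError):
        fit_logistic_ml(X, y)
    # the advised penalized fit succeeds
    fit = fit_logistic_penalized(X, y, lam=1.0,
                                 mask=np.array([False, True]))
    assert fit.converged


# --------------------------------------------------------------------------
# Penalized fitting
# --------------------------------------------------------------------------

def test_lambda_zero_equals_ml():
    X, y = _random_dataset(3)
    mask = np.zeros(8, dtype=bool)
    mask[4:] = True
    ml = fit_logistic_ml(X, y)
    pen = fit_logistic_penalized(X, y, lam=0.0, mask=mask)
    np.testing.assert_allclose(pen.beta, ml.beta, rtol=1e-6)
    np.testing.assert_allclose(pen.cov, ml.cov, rtol=1e-6)


def test_huge_lambda_kills_masked_terms_only():
    X, y = _random_dataset(5)
    mask = np.zeros(8, dtype=bool)
    mask[4:] = True
    pen = fit_logistic_penalized(X, y, lam=1e8, mask=mask)
    assert np.abs(pen.beta[mask]).max() < 1e-4
    sub = fit_logistic_ml(X[:, ~mask], y)
    np.testing.assert_allclose(pen.beta[~mask], sub.beta, atol=1e-3)


def test_masked_magnitudes_shrink_monotonically_in_lambda():
    X, y = _random_dataset(9)
    mask = np.zeros(8, dtype=bool)
    mask[4:] = True
    norms = []
    for lam in [0.0, 1.0, 4.0, 16.0, 64.0, 256.0]:
        fit = fit_logistic_penalized(X, y, lam=lam, mask=mask)
        norms.append(np.linalg.norm(fit.beta[mask]))
    assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))


def test_negative_lambda_rejected():
    X, y = _random_dataset(1)
    with pytest.raises(ValueError):
        fit_logistic_penalized(X, y, lam=-1.0)


# --------------------------------------------------------------------------
# Penalty selection
# --------------------------------------------------------------------------

def test_singleton_grid_returns_it():
    X, y = _random_dataset(2, n=300)
    assert select_penalty(X, y, np.zeros(8, bool), grid=[0.0]) == 0.0


def test_selection_deterministic_given_seed():
    X, y = _random_dataset(4, n=400)
    mask = np.zeros(8, bool)
    mask[5:] = True
    grid = [0.0, 4.0, 64.0]
    a = select_penalty(X, y, mask, grid=grid, folds=5, seed=11)
    b = select_penalty(X, y, mask, grid=grid, folds=5, seed=11)
    assert a == b


def test_null_interactions_push_lambda_high():
    """When the masked columns carry no signal, cross-validation should
    usually choose a heavy penalty for them."""
    rng = np.random.default_rng(12)
    hits = 0
    reps = 15
    for r in range(reps):
        n = 1500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 5))])
        beta = np.array([-1.0, 0.6, -0.4, 0.0, 0.0, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        mask = np.array([False, False, False, True, True, True])
        lam = select_penalty(X, y, mask, grid=[0.0, 4.0, 64.0, 256.0],
                             folds=5, seed=r)
        hits += lam >= 64.0
    assert hits >= reps // 2


# --------------------------------------------------------------------------
# Effect reporting and pooling
# --------------------------------------------------------------------------

def test_or_closed_form_arithmetic():
    fit = ModelFit(beta=np.array([0.0, -0.0408]),
                   cov=np.diag([0.0, 0.0186 ** 2]),
                   names=["intercept", "treatment"])
    res = extract_or(fit, "treatment")
    assert res["or"] == pytest.approx(np.exp(-0.0408), rel=1e-12)
    assert res["ci_low"] == pytest.approx(np.exp(-0.0408 - 1.96 * 0.0186),
                                          rel=1e-12)
    assert res["ci_high"] == pytest.approx(np.exp(-0.0408 + 1.96 * 0.0186),
                                           rel=1e-12)
    assert 0.92 < res["ci_low"] < 0.93
    assert 0.99 < res["ci_high"] < 1.00


def test_zero_coefficient_gives_unit_or():
    fit = ModelFit(beta=np.array([0.3, 0.0]), cov=np.zeros((2, 2)),
                   names=["intercept", "treatment"])
    res = extract_or(fit, "treatment")
    assert res["or"] == 1.0
    assert res["ci_low"] == res["ci_high"] == 1.0


def test_percentile_contrast_for_quadratic_term(small_analysis):
    fit = fit_adjusted(small_analysis)
    res = percentile_or(fit, "ais_headneck", small_analysis)
    q75, q50 = (np.quantile(small_analysis["ais_headneck"], q)
                for q in (0.75, 0.50))
    expected = np.exp(fit.coef("ais_headneck") * (q75 - q50)
                      + fit.coef("ais_headneck_sq") * (q75 ** 2 - q50 ** 2))
    assert res["or"] == pytest.approx(expected, rel=1e-10)


def test_rubin_pooling_widens_variance():
    X, y = _random_dataset(6)
    f1 = fit_logistic_ml(X, y)
    X2, y2 = _random_dataset(60)
    f2 = fit_logistic_ml(X2, y2)
    f2.names = f1.names
    pooled = pool_fits([f1, f2])
    np.testing.assert_allclose(pooled.beta, (f1.beta + f2.beta) / 2)
    within = (np.diag(f1.cov) + np.diag(f2.cov)) / 2
    assert np.all(np.diag(pooled.cov) >= within - 1e-12)


def test_interaction_fit_roundtrips_through_json(small_analysis):
    fit = fit_interactions(small_analysis, lam=4.0)
    back = ModelFit.from_json(fit.to_json())
    np.testing.assert_allclose(back.beta, fit.beta)
    np.testing.assert_allclose(back.cov, fit.cov)
    assert back.names == fit.names
    assert back.with_interactions
    assert back.spec.centers == fit.spec.centers
    mask = interaction_mask(fit.names)
    assert mask.sum() == 5
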