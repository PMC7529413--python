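"""Lagged designs, per-pixel OLS, and ASO multi-task learning."""

import numpy as np
import pytest

from stgranger import (
    build_lagged_design,
    fit_aso_mtl,
    fit_ols,
    predict,
)
from stgranger.regression import build_design_stack


def ar1_series(rng, T, a=0.5):
    x = np.empty(T)
    x[0] = rng.standard_normal() / np.sqrt(1 - a**2)
    for t in range(1, T):
        x[t] = a * x[t - 1] + rng.standard_normal()
    return x


def random_designs(rng, n_pixels, T=166, P=10, full=True):
    out = []
    for _ in range(n_pixels):
        y = ar1_series(rng, T)
        x2 = ar1_series(rng, T)
        x1 = ar1_series(rng, T) if full else None
        out.append(build_lagged_design(y, x2, x1, P=P))
    return out


class TestBuildLaggedDesign:
    def test_dimensions_at_study_conditions(self):
        rng = np.random.default_rng(0)
        y, x1, x2 = rng.standard_normal((3, 166))
        base = build_lagged_design(y, x2, P=10, model_kind="base")
        full = build_lagged_design(y, x2, x1, P=10)
        assert (base.n_samples, base.n_coeffs) == (156, 21)
        assert (full.n_samples, full.n_coeffs) == (156, 31)

    def test_hand_example_lag_one(self):
        d = build_lagged_design(
            np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]), P=1, model_kind="base"
        )
        np.testing.assert_array_equal(d.X, [[1, 1, 4], [1, 2, 5]])
        np.testing.assert_array_equal(d.y, [2, 3])

    def test_no_instantaneous_predictor(self):
        # the lag-1 column of the cause must be its t-1 value, never t
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(30)
        d = build_lagged_design(rng.standard_normal(30), rng.standard_normal(30), x1, P=2)
        j = d.columns.index("x_cause_lag1")
        np.testing.assert_array_equal(d.X[:, j], x1[1:-1])

    def test_series_too_short_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="series too short"):
            build_lagged_design(
                rng.standard_normal(10), rng.standard_normal(10), rng.standard_normal(10), P=10
            )

    def test_unidentifiable_stack_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="series too short"):
            build_design_stack(
                rng.standard_normal((30, 2)),
                rng.standard_normal((30, 2)),
                rng.standard_normal((30, 2)),
                P=10,
            )


class TestOLS:
    def test_exact_linear_target_zero_residuals(self):
        rng = np.random.default_rng(3)
        d = random_designs(rng, 1)[0]
        w_true = rng.standard_normal(d.n_coeffs)
        d.y = d.X @ w_true
        _, fit, flag = fit_ols(d)
        assert not flag
        assert np.abs(fit.resid).max() < 1e-10

    def test_duplicate_column_flagged_rank_deficient(self):
        rng = np.random.default_rng(4)
        d = random_designs(rng, 1)[0]
        d.X[:, 5] = d.X[:, 6]
        _, _, flag = fit_ols(d)
        assert flag

    def test_noise_overfit_matches_expectation(self):
        # regressing white noise on k coefficients gives E[R^2] = (k-1)/(N-1)
        rng = np.random.default_rng(5)
        N, k, P = 156, 21, 10
        r2s = []
        for _ in range(300):
            d = build_lagged_design(
                rng.standard_normal(166), rng.standard_normal(166), P=P, model_kind="base"
            )
            _, fit, _ = fit_ols(d)
            sst = ((d.y - d.y.mean()) ** 2).sum()
            r2s.append(1 - fit.sse / sst)
        assert abs(np.mean(r2s) - (k - 1) / (N - 1)) < 0.02

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        d = random_designs(rng, 1)[0]
        w, fit, _ = fit_ols(d)
        ref = sm.OLS(d.y, d.X).fit()
        np.testing.assert_allclose(w, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.resid, ref.resid, atol=1e-8)


class TestPredict:
    def test_zero_and_intercept_only_weights(self):
        rng = np.random.default_rng(7)
        d = random_designs(rng, 1)[0]
        assert np.all(predict(np.zeros(d.n_coeffs), d).yhat == 0)
        w = np.zeros(d.n_coeffs)
        w[0] = 2.5
        np.testing.assert_allclose(predict(w, d).yhat, 2.5)

    def test_ols_residuals_orthogonal_to_columns(self):
        rng = np.random.default_rng(8)
        d = random_designs(rng, 1)[0]
        w, fit, _ = fit_ols(d)
        assert np.abs(d.X.T @ fit.resid).max() < 1e-8

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        d = random_designs(rng, 1)[0]
        with pytest.raises(ValueError, match="dimension"):
            predict(np.zeros(d.n_coeffs + 1), d)


class TestASOMultiTask:
    def test_lambda_zero_reproduces_per_pixel_ols(self):
        rng = np.random.default_rng(10)
        designs = random_designs(rng, 10)
        _, fit = fit_aso_mtl(designs, lam=0.0)
        sse_mtl = float((fit.resid**2).sum())
        sse_ols = sum(float(fit_ols(d)[1].sse) for d in designs)
        assert abs(sse_mtl - sse_ols) < 1e-6

    def test_single_pixel_full_subspace_matches_ols(self):
        rng = np.random.default_rng(11)
        d = random_designs(rng, 1)
        w, fit = fit_aso_mtl(d, lam=0.0, h=d[0].n_coeffs)
        _, ref, _ = fit_ols(d[0])
        np.testing.assert_allclose(fit.yhat[0], ref.yhat, atol=1e-6)

    def test_theta_rows_orthonormal(self):
        rng = np.random.default_rng(12)
        w, _ = fit_aso_mtl(random_designs(rng, 6), lam=0.5, h=4)
        gram = w.Theta @ w.Theta.T
        assert np.abs(gram - np.eye(4)).max() <= 1e-8

    def test_objective_non_increasing_across_alternations(self):
        rng = np.random.default_rng(13)
        w, _ = fit_aso_mtl(random_designs(rng, 8), lam=1.0, max_iter=10)
        hist = np.array(w.objective_history)
        assert np.all(np.diff(hist) <= 1e-9 * np.abs(hist[:-1]) + 1e-9)

    def test_regularization_pulls_shared_pixels_together(self):
        # pixels generated from one shared weight vector: larger lambda
        # shrinks the pixel-specific component, so fitted weights converge
        rng = np.random.default_rng(14)
        P, T, L = 3, 60, 12
        w_true = rng.standard_normal(1 + 2 * P)
        designs = []
        for _ in range(L):
            y0 = rng.standard_normal(T)
            x2 = rng.standard_normal(T)
            d = build_lagged_design(y0, x2, P=P, model_kind="base")
            d.y = d.X @ w_true + 0.5 * rng.standard_normal(d.n_samples)
            designs.append(d)
        spreads = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            w, _ = fit_aso_mtl(designs, lam=lam, h=2)
            diffs = w.W[:, None, :] - w.W[None, :, :]
            spreads.append(np.abs(diffs).max())
        assert all(a >= b - 1e-9 for a, b in zip(spreads, spreads[1:]))

    def test_invalid_arguments_rejected(self):
        rng = np.random.default_rng(15)
        designs = random_designs(rng, 2)
        with pytest.raises(ValueError, match="lam"):
            fit_aso_mtl(designs, lam=-1.0)
        with pytest.raises(ValueError, match="subspace"):
            fit_aso_mtl(designs, h=0)

    def test_nested_models_full_sse_never_larger(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            y = ar1_series(rng, 80)
            x1 = ar1_series(rng, 80)
            x2 = ar1_series(rng, 80)
            base = build_lagged_design(y, x2, P=5, model_kind="base")
            full = build_lagged_design(y, x2, x1, P=5)
            assert float(fit_ols(full)[1].sse) <= float(fit_ols(base)[1].sse) + 1e-9

    def test_design_stack_matches_single_pixel_builder(self):
        rng = np.random.default_rng(17)
        Y = rng.standard_normal((40, 3))
        X1 = rng.standard_normal((40, 3))
        X2 = rng.standard_normal((40, 3))
        stack = build_design_stack(Y, [X2], X1, P=4)
        single = build_lagged_design(Y[:, 1], X2[:, 1], X1[:, 1], P=4)
        np.testing.assert_array_equal(stack[1].X, single.X)
        np.testing.assert_array_equal(stack[1].y, single.y)
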