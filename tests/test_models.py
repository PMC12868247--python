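"""Calibration models against closed-form and scikit-learn oracles."""

import numpy as np
import pytest

from brixcal.models import (
    LassoConvergenceError,
    LassoRegression,
    PLSRegression,
    RidgeRegression,
    fit_lasso,
    fit_plsr,
    fit_ridge,
    lasso_alpha_grid,
    search_lasso_alpha,
    select_plsr_components,
)


def random_problem(seed, n=30, p=8, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = 5.0 + X @ beta + noise * rng.standard_normal(n)
    return X, y


def ols_fit(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[0], coef[1:]


class TestPLSR:
    def test_single_column_one_component_is_simple_regression(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = 2.0 + 3.0 * x + 0.01 * rng.standard_normal(20)
        res = fit_plsr(x[:, None], y, n_components=1)
        slope, intercept = np.polyfit(x, y, 1)
        assert np.isclose(res.coefficients[0], slope, rtol=1e-10)
        assert np.isclose(res.intercept, intercept, rtol=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_full_rank_equals_ols(self, seed):
        X, y = random_problem(seed, n=40, p=6)
        res = fit_plsr(X, y, n_components=6)
        b0, b = ols_fit(X, y)
        assert np.allclose(res.coefficients, b, rtol=1e-6, atol=1e-9)
        assert np.isclose(res.intercept, b0, rtol=1e-6)

    def test_scores_mutually_orthogonal(self):
        X, y = random_problem(7, n=50, p=20)
        res = fit_plsr(X, y, n_components=8)
        T = res.extras["x_scores"]
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_runs_at_study_scale(self, default_dataset):
        spectra, ref = default_dataset
        res = fit_plsr(spectra.values[:90], ref.ssc[:90], n_components=10)
        assert res.coefficients.size == 486
        assert res.hyperparams["n_components"] == 10

    def test_components_truncated_with_warning_on_rank_deficiency(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((15, 2))
        X = base @ rng.standard_normal((2, 6))  # rank 2
        y = X[:, 0] + 0.01 * rng.standard_normal(15)
        with pytest.warns(UserWarning, match="truncated"):
            res = fit_plsr(X, y, n_components=5)
        assert res.hyperparams["n_components"] <= 3

    def test_zero_variance_y_rejected(self):
        X, _ = random_problem(5)
        with pytest.raises(ValueError, match="zero variance"):
            fit_plsr(X, np.full(X.shape[0], 3.0), n_components=2)

    def test_matches_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression as SkPLS

        X, y = random_problem(11, n=35, p=12, noise=0.5)
        res = fit_plsr(X, y, n_components=5)
        sk = SkPLS(n_components=5, scale=False).fit(X, y)
        assert np.allclose(res.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_band_permutation_equivariance(self):
        X, y = random_problem(13, n=30, p=9)
        perm = np.random.default_rng(0).permutation(9)
        a = fit_plsr(X, y, n_components=4)
        b = fit_plsr(X[:, perm], y, n_components=4)
        assert np.allclose(a.predict(X), b.predict(X[:, perm]), atol=1e-9)

    def test_sample_order_invariance(self):
        X, y = random_problem(17)
        perm = np.random.default_rng(1).permutation(len(y))
        a = fit_plsr(X, y, n_components=3)
        b = fit_plsr(X[perm], y[perm], n_components=3)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-9)


class TestSelectComponents:
    def test_exact_low_rank_structure_found(self):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal((60, 3))
        X = scores @ rng.standard_normal((3, 20))
        y = scores @ np.array([1.0, -2.0, 0.5])
        k = select_plsr_components(X, y, n_min=2, n_max=10, validation=0)
        assert k == 3  # RMSE ~ 0 from 3 on; tie rule picks the smallest

    def test_degenerate_range_returns_value(self):
        X, y = random_problem(8, n=25, p=6)
        assert select_plsr_components(X, y, n_min=4, n_max=4, validation=0) == 4


class TestLasso:
    def test_alpha_above_lambda_max_zeroes_everything(self):
        X, y = random_problem(21, n=40, p=6)
        xs = (X - X.mean(0)) / X.std(0)
        lam_max = np.max(np.abs(xs.T @ (y - y.mean()))) / len(y)
        res = fit_lasso(X, y, alpha=lam_max * 1.01)
        assert np.all(res.coefficients == 0.0)
        assert np.isclose(res.intercept, y.mean())

    def test_orthonormal_design_soft_threshold_closed_form(self):
        # columns orthogonal with population variance 1 -> standardisation
        # is a no-op and each coefficient is soft-thresholded OLS
        rng = np.random.default_rng(22)
        n, p = 32, 5
        M = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:] * np.sqrt(n)  # zero-mean, orthogonal, population var 1
        beta = np.array([2.0, -1.0, 0.05, 0.0, 0.6])
        y = 1.0 + X @ beta
        alpha = 0.3
        res = fit_lasso(X, y, alpha=alpha)
        ols = X.T @ (y - y.mean()) / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - alpha, 0.0)
        assert np.allclose(res.coefficients, expected, atol=1e-6)

    def test_vanishing_penalty_approaches_ols(self):
        X, y = random_problem(23, n=50, p=5, noise=0.2)
        res = fit_lasso(X, y, alpha=1e-8)
        _, b = ols_fit(X, y)
        assert np.allclose(res.coefficients, b, rtol=1e-4, atol=1e-6)

    def test_kkt_conditions_hold_at_solution(self):
        X, y = random_problem(24, n=45, p=12, noise=0.5)
        alpha = 0.05
        res = fit_lasso(X, y, alpha=alpha, tol=1e-9)
        xm, xs = res.scaling["x_mean"], res.scaling["x_sd"]
        Xs = (X - xm) / xs
        beta = res.extras["beta_standardized"]
        r = (y - y.mean()) - Xs @ beta
        g = Xs.T @ r / len(y)
        tol = 1e-6
        assert np.all(np.abs(g[beta == 0]) <= alpha + tol)
        nz = beta != 0
        assert np.allclose(g[nz], alpha * np.sign(beta[nz]), atol=tol)

    def test_matches_sklearn_on_standardised_data(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(25)
        X = rng.standard_normal((40, 8))
        X = (X - X.mean(0)) / X.std(0)  # our internal standardisation is a no-op
        y = 3.0 + X[:, 0] - 2 * X[:, 3] + 0.1 * rng.standard_normal(40)
        res = fit_lasso(X, y, alpha=0.02, tol=1e-10)
        sk = Lasso(alpha=0.02, tol=1e-12, max_iter=200_000).fit(X, y)
        assert np.allclose(res.coefficients, sk.coef_, atol=1e-6)
        assert np.isclose(res.intercept, sk.intercept_, atol=1e-6)

    def test_nonconvergence_raises_with_iteration_count(self):
        X, y = random_problem(26, n=30, p=10)
        with pytest.raises(LassoConvergenceError, match="2 cycles"):
            fit_lasso(X, y, alpha=1e-6, tol=1e-14, max_iter=2)

    def test_sample_order_invariance(self):
        X, y = random_problem(27)
        perm = np.random.default_rng(2).permutation(len(y))
        a = fit_lasso(X, y, alpha=0.05, tol=1e-10)
        b = fit_lasso(X[perm], y[perm], alpha=0.05, tol=1e-10)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-7)


class TestSearchLassoAlpha:
    def test_grid_includes_endpoints_and_count(self):
        grid = lasso_alpha_grid(1e-5, 1.0, 50)
        assert grid.size == 50
        assert np.isclose(grid[0], 1e-5)
        assert np.isclose(grid[-1], 1.0)

    def test_sparse_support_recovered(self):
        rng = np.random.default_rng(30)
        X = rng.standard_normal((60, 20))
        y = 4.0 + 2.0 * X[:, 3] - 1.5 * X[:, 11] + 0.05 * rng.standard_normal(60)
        alpha = search_lasso_alpha(X, y, validation=0)
        res = fit_lasso(X, y, alpha=alpha)
        support = set(np.flatnonzero(res.coefficients != 0))
        assert {3, 11} <= support

    def test_single_point_grid_returns_lower_bound(self):
        X, y = random_problem(31)
        alpha = search_lasso_alpha(X, y, n_grid=1, grid_lo=1e-3, validation=0)
        assert np.isclose(alpha, 1e-3)


class TestRidge:
    def test_zero_alpha_full_rank_equals_ols(self):
        X, y = random_problem(41, n=40, p=5)
        res = fit_ridge(X, y, alpha=0.0)
        b0, b = ols_fit(X, y)
        assert np.allclose(res.coefficients, b, rtol=1e-8)
        assert np.isclose(res.intercept, b0, rtol=1e-8)

    def test_infinite_alpha_limit_shrinks_to_mean(self):
        X, y = random_problem(42)
        res = fit_ridge(X, y, alpha=1e12)
        assert np.all(np.abs(res.coefficients) < 1e-6)
        assert np.isclose(res.intercept, y.mean(), atol=1e-4)

    def test_two_predictor_hand_inversion(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        alpha = 0.5
        Xc = X - X.mean(0)
        yc = y - y.mean()
        G = Xc.T @ Xc + alpha * np.eye(2)
        # 2x2 inverse by hand: [[a,b],[c,d]]^-1 = [[d,-b],[-c,a]]/det
        det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
        Ginv = np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det
        expected = Ginv @ (Xc.T @ yc)
        res = fit_ridge(X, y, alpha=alpha)
        assert np.allclose(res.coefficients, expected, atol=1e-12)

    def test_normal_equations_satisfied(self):
        X, y = random_problem(43, n=35, p=10)
        alpha = 0.7
        res = fit_ridge(X, y, alpha=alpha)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        resid = (Xc.T @ Xc + alpha * np.eye(10)) @ res.coefficients - Xc.T @ yc
        assert np.linalg.norm(resid) < 1e-8

    def test_singular_design_at_zero_alpha_rejected(self):
        rng = np.random.default_rng(44)
        X = rng.standard_normal((10, 20))  # p > n
        y = rng.standard_normal(10)
        with pytest.raises(np.linalg.LinAlgError, match="alpha > 0"):
            fit_ridge(X, y, alpha=0.0)

    def test_matches_sklearn(self):
        from sklearn.linear_model import Ridge

        X, y = random_problem(45, n=30, p=12)
        res = fit_ridge(X, y, alpha=0.3)
        sk = Ridge(alpha=0.3).fit(X, y)
        assert np.allclose(res.coefficients, sk.coef_, atol=1e-8)
        assert np.isclose(res.intercept, sk.intercept_, atol=1e-8)


class TestPredictAndResults:
    def test_zero_coefficient_model_is_constant(self):
        X, y = random_problem(51)
        res = fit_lasso(X, y, alpha=1e3)
        assert np.allclose(res.predict(X), res.intercept)

    def test_fittedvalues_equal_predict_on_training_data(self):
        X, y = random_problem(52)
        res = fit_ridge(X, y, alpha=0.1)
        assert np.allclose(res.fittedvalues, res.predict(X))

    def test_dimension_mismatch_rejected(self):
        X, y = random_problem(53, p=6)
        res = fit_ridge(X, y, alpha=0.1)
        with pytest.raises(ValueError, match="bands"):
            res.predict(X[:, :4])

    def test_summary_mentions_method_and_hyperparams(self):
        X, y = random_problem(54)
        res = fit_plsr(X, y, n_components=3)
        text = res.summary()
        assert "PLSR" in text and "n_components=3" in text

    def test_from_spectra_constructor(self, default_dataset):
        spectra, ref = default_dataset
        model = RidgeRegression.from_spectra(spectra, ref)
        res = model.fit(alpha=1e-3)
        assert res.coefficients.size == spectra.n_bands
        assert np.array_equal(res.wavelengths, spectra.wavelengths)
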