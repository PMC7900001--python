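"""OLS/lasso closed forms, penalty selection, optimism-corrected R²."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from outcomecast import (
    default_lambda_grid,
    fit_lasso,
    fit_ols,
    lasso_lambda_max,
    loocv_corrected_r2,
    select_lambda_loocv,
)


class TestOls:
    def test_exact_linear_relation_gives_zero_residuals(self, rng):
        X = rng.standard_normal((30, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 0.25])
        fit = fit_ols(X, y)
        np.testing.assert_allclose(fit.predict(X), y, atol=1e-10)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(3.0, 1.0, 40)
        fit = fit_ols(np.empty((40, 0)), y)
        assert fit.intercept == pytest.approx(y.mean())

    def test_normal_equations_closed_form(self):
        # x = (0,1,2), y = (1,2,4): slope 3/2, intercept ybar - slope*xbar
        fit = fit_ols(np.array([[0.0], [1.0], [2.0]]),
                      np.array([1.0, 2.0, 4.0]))
        assert fit.coefficients[0] == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(5.0 / 6.0)

    def test_rank_deficiency_flagged(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([x, 2 * x])
        fit = fit_ols(X, x)
        assert fit.rank_deficient


class TestLasso:
    def test_zero_penalty_matches_ols(self, rng):
        X = rng.standard_normal((50, 4))
        y = X @ np.array([1.0, 0.5, 0.0, -0.3]) + rng.standard_normal(50)
        ols = fit_ols(X, y)
        lasso = fit_lasso(X, y, 0.0)
        np.testing.assert_allclose(lasso.coefficients, ols.coefficients,
                                   atol=1e-6)

    def test_lambda_max_kkt_zeroes_all_slopes(self, rng):
        X = rng.standard_normal((60, 5)) * np.array([1, 3, 0.5, 2, 1])
        y = X @ np.array([1.0, 0.2, 0, 0, -0.5]) + rng.standard_normal(60)
        lam_max = lasso_lambda_max(X, y)
        fit = fit_lasso(X, y, lam_max * (1 + 1e-10))
        assert np.all(fit.coefficients == 0.0)
        assert fit.intercept == pytest.approx(y.mean())
        # just below lambda_max at least one slope activates
        fit2 = fit_lasso(X, y, lam_max * 0.99)
        assert np.any(fit2.coefficients != 0.0)

    def test_single_predictor_soft_threshold(self, rng):
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std()
        y = 0.9 * x + 0.3 * rng.standard_normal(200)
        b = fit_ols(x[:, None], y).coefficients[0]
        for lam in (0.1, 0.3, 0.6):
            if lam < abs(b):
                expect = np.sign(b) * (abs(b) - lam)
                got = fit_lasso(x[:, None], y, lam).coefficients[0]
                assert got == pytest.approx(expect, abs=1e-8)

    def test_matches_sklearn_across_penalties(self, rng):
        # independent implementation of the same objective
        X = rng.standard_normal((80, 6)) @ np.diag([1, 2, 0.5, 1, 3, 1])
        y = X @ np.array([1, 0, -0.5, 0.3, 0, 0.2]) + rng.standard_normal(80)
        mu, sd = X.mean(0), X.std(0)
        Z = (X - mu) / sd
        for lam in (0.02, 0.1, 0.5):
            mine = fit_lasso(X, y, lam)
            sk = Lasso(alpha=lam, tol=1e-12, max_iter=200_000).fit(Z, y)
            np.testing.assert_allclose(mine.coefficients, sk.coef_ / sd,
                                       atol=1e-6)

    def test_orthonormal_design_soft_thresholds_every_coefficient(self, rng):
        # on an orthonormal design the lasso solution is exactly the
        # soft-thresholded OLS solution, coefficient by coefficient
        # QR against a leading ones column yields centred orthonormal
        # columns; scaled by sqrt(n) they are exactly standardized
        n, p = 64, 4
        M = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:] * np.sqrt(n)
        beta = np.array([1.2, -0.7, 0.25, 0.0])
        y = X @ beta
        b_ols = fit_ols(X, y).coefficients
        G = (X.T @ X) / n
        np.testing.assert_allclose(G, np.eye(p), atol=1e-8)
        for lam in (0.1, 0.5, 0.9):
            got = fit_lasso(X, y, lam).coefficients
            expect = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
            np.testing.assert_allclose(got, expect, atol=1e-7)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_lasso(rng.standard_normal((10, 2)), rng.standard_normal(10),
                      -0.1)


class TestSelectLambda:
    def test_singleton_grid_returned(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        assert select_lambda_loocv(X, y, lam_grid=[0.37]) == 0.37

    def test_null_data_favours_heavy_penalty(self):
        # with y independent of X, min-MSE LOOCV should usually land on the
        # empty model at lambda_max; the selection is noisy (no 1-SE rule),
        # so only a majority — not near-certainty — can be required
        empty = 0
        maxcoefs = []
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = r.standard_normal((50, 5))
            y = r.standard_normal(50)
            lam = select_lambda_loocv(X, y, n_lambda=60)
            coef = fit_lasso(X, y, lam).coefficients
            maxcoefs.append(np.max(np.abs(coef)))
            if np.max(np.abs(coef)) < 0.05:
                empty += 1
        assert empty / n_seeds > 0.5
        assert np.mean(maxcoefs) < 0.15

    def test_strong_signal_beats_variance_baseline(self, rng):
        X = rng.standard_normal((100, 5))
        beta = np.array([1.5, 1.0, 0.5, 0.0, 0.0])
        sig_var = float(beta @ beta)
        noise = np.sqrt(sig_var / 9.0)  # population R² = 0.9
        y = X @ beta + noise * rng.standard_normal(100)
        lam, lams, mse = select_lambda_loocv(X, y, return_mse=True)
        assert mse.min() < np.var(y)

    def test_grid_defaults_span_three_decades(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        grid = default_lambda_grid(X, y)
        assert grid.size == 100
        assert grid[0] == pytest.approx(lasso_lambda_max(X, y))
        assert grid[-1] == pytest.approx(grid[0] * 1e-3)


class TestCorrectedR2:
    def test_noiseless_linear_outcome_gives_unity(self, rng):
        X = rng.standard_normal((40, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        perf = loocv_corrected_r2(X, y, method="ols")
        assert perf.r2_corrected == pytest.approx(1.0, abs=1e-8)
        assert perf.r2_apparent == pytest.approx(1.0, abs=1e-8)
        # lasso's grid floor (0.001 * lambda_max) leaves a tiny bias
        perf = loocv_corrected_r2(X, y, method="lasso", n_lambda=30)
        assert perf.r2_corrected == pytest.approx(1.0, abs=1e-3)

    def test_apparent_exceeds_corrected_in_expectation_on_null(self):
        apps, corrs = [], []
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 5))
            y = r.standard_normal(40)
            perf = loocv_corrected_r2(X, y, method="ols")
            apps.append(perf.r2_apparent)
            corrs.append(perf.r2_corrected)
        assert np.mean(apps) > np.mean(corrs)
        assert np.mean(apps) > 0  # resubstitution optimism is real

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_corrected_r2(rng.standard_normal((4, 2)),
                               rng.standard_normal(4))

    def test_zero_variance_outcome_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_corrected_r2(rng.standard_normal((10, 2)), np.ones(10),
                               method="ols")

    def test_nested_and_fixed_penalty_modes_agree_on_strong_signal(self, rng):
        X = rng.standard_normal((60, 4))
        y = X @ np.array([2.0, 1.0, 0, 0]) + 0.2 * rng.standard_normal(60)
        nested = loocv_corrected_r2(X, y, nested=True, n_lambda=30)
        fixed = loocv_corrected_r2(X, y, nested=False, n_lambda=30)
        assert nested.r2_corrected == pytest.approx(fixed.r2_corrected,
                                                    abs=0.02)
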