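"""Linear and lasso regression with optimism-corrected R² via LOOCV.

The lasso objective is the standard elastic-net-style parameterization

    (1 / 2n) * ||y - b0 - X beta||^2 + lambda * sum_j |beta_j|

with the intercept unpenalized and predictors standardized internally
(coefficients are reported on the original scale).  The penalty is chosen
to minimize leave-one-out mean squared error, and the optimism-corrected
R² refits the *entire* procedure — including penalty selection — on every
leave-one-out training set, so no information leaks from the held-out row.

Coordinate descent runs on the standardized Gram matrix, which makes a
full penalty path an O(p^2) operation per sweep; the nested double-LOOCV
loop maintains fold-level sufficient statistics by rank-one downdates.
The hot loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "LinearFit",
    "CvPerformance",
    "fit_ols",
    "fit_lasso",
    "lasso_lambda_max",
    "default_lambda_grid",
    "select_lambda_loocv",
    "loocv_corrected_r2",
]

_TOL = 1e-7
#: looser tolerance for penalty-*selection* sweeps only: the LOO MSE curve
#: is flat at this scale, while final fits keep the strict tolerance
_TOL_SELECT = 1e-4
_MAXIT = 10_000


@dataclass
class LinearFit:
    intercept: float
    coefficients: np.ndarray
    lam: float = 0.0
    rank_deficient: bool = False
    columns: list | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients


@dataclass
class CvPerformance:
    outcome: str | None
    timepoint_label: str | None
    n_used: int
    r2_apparent: float
    r2_corrected: float
    method: str
    lam: float | None = None


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_sweep(G, c, lam, beta, active_only):
    """One coordinate-descent sweep; returns the largest coefficient change.

    With ``active_only`` the sweep touches only currently non-zero
    coefficients (the glmnet active-set strategy); zero coefficients are
    skipped inside the Gram dot product either way.
    """
    p = G.shape[0]
    maxd = 0.0
    for j in range(p):
        if active_only and beta[j] == 0.0:
            continue
        gjj = G[j, j]
        if gjj <= 0.0:
            beta[j] = 0.0
            continue
        rho = c[j] + gjj * beta[j]
        for kk in range(p):
            b = beta[kk]
            if b != 0.0:
                rho -= G[j, kk] * b
        if rho > lam:
            bn = (rho - lam) / gjj
        elif rho < -lam:
            bn = (rho + lam) / gjj
        else:
            bn = 0.0
        d = abs(bn - beta[j])
        if d > maxd:
            maxd = d
        beta[j] = bn
    return maxd


@njit(cache=True)
def _cd_gram_path(G, c, lams, tol, maxit):
    """Lasso path by coordinate descent on a standardized Gram matrix.

    G = X'X/n and c = X'y/n for column-standardized X and centred y;
    solutions are warm-started along the (descending) lambda grid.
    Inner iterations run over the active set, with a full sweep to
    confirm convergence and re-screen.
    """
    p = G.shape[0]
    B = np.zeros((lams.size, p))
    beta = np.zeros(p)
    for li in range(lams.size):
        lam = lams[li]
        it = 0
        while it < maxit:
            maxd = _cd_sweep(G, c, lam, beta, False)
            it += 1
            if maxd < tol:
                break
            while it < maxit:
                maxd = _cd_sweep(G, c, lam, beta, True)
                it += 1
                if maxd < tol:
                    break
        B[li] = beta
    return B


@njit(cache=True)
def _fold_stats(S1, S2, Sy, ys, nn):
    """Standardized Gram, covariance-with-y and scaling from raw sums."""
    p = S1.size
    m = S1 / nn
    ybar = ys / nn
    sd = np.empty(p)
    for j in range(p):
        v = S2[j, j] / nn - m[j] * m[j]
        sd[j] = np.sqrt(v) if v > 1e-24 else 0.0
    G = np.zeros((p, p))
    c = np.zeros(p)
    for j in range(p):
        if sd[j] == 0.0:
            continue
        c[j] = (Sy[j] / nn - m[j] * ybar) / sd[j]
        for kk in range(p):
            if sd[kk] == 0.0:
                continue
            G[j, kk] = (S2[j, kk] / nn - m[j] * m[kk]) / (sd[j] * sd[kk])
    return G, c, m, sd, ybar


@njit(cache=True)
def _predict_std(beta, x, m, sd, ybar):
    pred = ybar
    for j in range(x.size):
        if sd[j] > 0.0:
            pred += beta[j] * (x[j] - m[j]) / sd[j]
    return pred


@njit(cache=True)
def _grid_from(lam_max, n_lam, lam_ratio):
    g = np.empty(n_lam)
    if lam_max <= 0.0:
        for i in range(n_lam):
            g[i] = 0.0
        return g
    lo = np.log(lam_max * lam_ratio)
    hi = np.log(lam_max)
    for i in range(n_lam):
        t = i / (n_lam - 1) if n_lam > 1 else 0.0
        g[i] = np.exp(hi + t * (lo - hi))  # descending
    return g


@njit(cache=True)
def _loocv_sse_path(S1, S2, Sy, ys, X, y, lams, tol, maxit):
    """Per-lambda LOO sum of squared prediction errors."""
    n, p = X.shape
    sse = np.zeros(lams.size)
    for i in range(n):
        s1 = S1 - X[i]
        s2 = S2 - np.outer(X[i], X[i])
        sy = Sy - X[i] * y[i]
        G, c, m, sd, ybar = _fold_stats(s1, s2, sy, ys - y[i], n - 1)
        B = _cd_gram_path(G, c, lams, tol, maxit)
        for li in range(lams.size):
            pred = _predict_std(B[li], X[i], m, sd, ybar)
            sse[li] += (y[i] - pred) ** 2
    return sse


@njit(cache=True)
def _best_lam_index(sse):
    """Arg-min with ties broken toward larger lambda (earlier index)."""
    best = 0
    for li in range(1, sse.size):
        if sse[li] < sse[best]:
            best = li
    return best


@njit(cache=True)
def _nested_loocv_lasso(X, y, n_lam, lam_ratio, tol, tol_select, maxit):
    """Leave-one-out predictions with the penalty re-selected per fold.

    For every held-out row i: on the remaining n-1 rows, build that fold's
    lambda grid from its own lambda_max, select lambda by an inner LOOCV,
    fit at the selected lambda, and predict row i.
    """
    n, p = X.shape
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    Sy = np.zeros(p)
    ys = 0.0
    for i in range(n):
        S1 += X[i]
        S2 += np.outer(X[i], X[i])
        Sy += X[i] * y[i]
        ys += y[i]

    preds = np.empty(n)
    for i in range(n):
        s1 = S1 - X[i]
        s2 = S2 - np.outer(X[i], X[i])
        sy = Sy - X[i] * y[i]
        yssum = ys - y[i]
        nn = n - 1
        Gf, cf, mf, sdf, ybarf = _fold_stats(s1, s2, sy, yssum, nn)
        lam_max = np.abs(cf).max()
        lams = _grid_from(lam_max, n_lam, lam_ratio)

        # inner LOOCV over the fold's rows
        sse = np.zeros(n_lam)
        for l in range(n):
            if l == i:
                continue
            t1 = s1 - X[l]
            t2 = s2 - np.outer(X[l], X[l])
            ty = sy - X[l] * y[l]
            G, c, m, sd, ybar = _fold_stats(t1, t2, ty, yssum - y[l], nn - 1)
            B = _cd_gram_path(G, c, lams, tol_select, maxit)
            for li in range(n_lam):
                pred = _predict_std(B[li], X[l], m, sd, ybar)
                sse[li] += (y[l] - pred) ** 2
        best = _best_lam_index(sse)

        Bf = _cd_gram_path(Gf, cf, lams[:best + 1], tol, maxit)
        preds[i] = _predict_std(Bf[best], X[i], mf, sdf, ybarf)
    return preds


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _as_2d(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_ols(X, y) -> LinearFit:
    """Ordinary least squares with an (implicit, unpenalized) intercept.

    Rank-deficient designs return the minimum-norm solution, flagged.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= 1:
        raise ValueError("need at least 2 rows")
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    return LinearFit(intercept=float(coef[0]), coefficients=coef[1:],
                     lam=0.0, rank_deficient=rank < p + 1)


def lasso_lambda_max(X, y) -> float:
    """Smallest penalty at which all lasso slopes are exactly zero."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    return float(np.abs(Z.T @ (y - y.mean())).max() / n)


def default_lambda_grid(X, y, n_lambda: int = 100,
                        lambda_ratio: float = 1e-3) -> np.ndarray:
    lam_max = lasso_lambda_max(X, y)
    return np.asarray(_grid_from(lam_max, n_lambda, lambda_ratio))


def fit_lasso(X, y, lam: float) -> LinearFit:
    """Coordinate-descent lasso at a single penalty.

    lam = 0 falls back to the exact least-squares solution.  Coefficients
    are computed on internally standardized predictors and reported on the
    original scale; constant columns get coefficient zero.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if lam == 0.0:
        fit = fit_ols(X, y)
        return fit
    S1 = X.sum(axis=0)
    S2 = X.T @ X
    Sy = X.T @ y
    G, c, m, sd, ybar = _fold_stats(S1, S2, Sy, y.sum(), n)
    B = _cd_gram_path(G, c, np.array([lam], dtype=float), _TOL, _MAXIT)
    beta_std = B[0]
    coef = np.where(sd > 0, beta_std / np.where(sd > 0, sd, 1.0), 0.0)
    intercept = ybar - float(coef @ m)
    return LinearFit(intercept=intercept, coefficients=coef, lam=float(lam))


def select_lambda_loocv(X, y, lam_grid=None, n_lambda: int = 100,
                        lambda_ratio: float = 1e-3,
                        return_mse: bool = False):
    """Penalty minimizing the leave-one-out MSE over a grid.

    Ties are broken toward the larger (sparser) penalty.  The default grid
    is 100 log-spaced values from lambda_max down to 0.001 * lambda_max.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for LOOCV")
    if lam_grid is None:
        lam_grid = default_lambda_grid(X, y, n_lambda, lambda_ratio)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty lambda grid")
    order = np.argsort(lam_grid)[::-1]  # descending
    lams = lam_grid[order]
    sse = _loocv_sse_path(X.sum(axis=0), X.T @ X, X.T @ y, y.sum(),
                          X, y, lams, _TOL_SELECT, _MAXIT)
    best = _best_lam_index(sse)
    lam_star = float(lams[best])
    if return_mse:
        return lam_star, lams, sse / n
    return lam_star


def _r2(y, yhat, ybar) -> float:
    tss = float(np.sum((y - ybar) ** 2))
    if tss == 0:
        raise ValueError("zero-variance outcome: R² undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


def _loo_ols_predictions(X, y):
    # exact closed form via leverages: e_i / (1 - h_ii)
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q ** 2, axis=1)
    fit = fit_ols(X, y)
    resid = y - fit.predict(X)
    denom = np.clip(1.0 - h, 1e-12, None)
    return y - resid / denom


def loocv_corrected_r2(X, y, method: str = "lasso", outcome=None,
                       timepoint_label=None, nested: bool = True,
                       n_lambda: int = 100, lambda_ratio: float = 1e-3
                       ) -> CvPerformance:
    """Apparent and LOOCV-corrected R².

    For the lasso with ``nested=True`` (default), the penalty is
    re-selected by an inner LOOCV inside every outer leave-one-out fold;
    ``nested=False`` keeps the full-data penalty (faster, slightly
    optimistic).  The corrected R² uses the full-sample mean in its
    denominator, so it may be negative — a model predicting worse than the
    sample mean.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 rows")
    ybar = float(y.mean())

    if method == "ols":
        fit = fit_ols(X, y)
        r2_app = _r2(y, fit.predict(X), ybar)
        preds = _loo_ols_predictions(X, y)
        lam_star = 0.0
    elif method == "lasso":
        lam_star = select_lambda_loocv(X, y, n_lambda=n_lambda,
                                       lambda_ratio=lambda_ratio)
        fit = fit_lasso(X, y, lam_star)
        r2_app = _r2(y, fit.predict(X), ybar)
        if nested:
            preds = _nested_loocv_lasso(X, y, n_lambda, lambda_ratio,
                                        _TOL, _TOL_SELECT, _MAXIT)
        else:
            preds = _loo_fixed_lam_predictions(X, y, lam_star)
    else:
        raise ValueError(f"unknown method {method!r}")

    r2_corr = _r2(y, preds, ybar)
    return CvPerformance(outcome=outcome, timepoint_label=timepoint_label,
                         n_used=n, r2_apparent=r2_app, r2_corrected=r2_corr,
                         method=method, lam=lam_star)


def _loo_fixed_lam_predictions(X, y, lam):
    n = X.shape[0]
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        fit = fit_lasso(X[mask], y[mask], lam)
        preds[i] = fit.predict(X[i:i + 1])[0]
    return preds
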