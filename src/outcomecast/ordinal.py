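"""Proportional-odds regression and the optimism-corrected c-statistic.

Ordinal outcomes are modeled with the cumulative-link model
P(Y <= j | x) = F(theta_j - x'beta) with strictly increasing thresholds
(F logistic for the analysis models, probit for the joint latent model).
Discrimination is measured by the generalized c-statistic — the
probability that, for a pair with different outcome levels, the model's
score ranks the higher-level member higher, ties counting one half — and
corrected for optimism by Harrell's bootstrap (40 repetitions by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit, expit, ndtr
from scipy.stats import rankdata
from statsmodels.miscmodels.ordinal_model import OrderedModel

log = logging.getLogger(__name__)

__all__ = ["OrdinalFit", "CStatResult", "fit_propodds", "c_statistic",
           "bootstrap_corrected_c"]


@dataclass
class OrdinalFit:
    thresholds: np.ndarray          # length J-1, strictly increasing
    coefficients: np.ndarray        # length p
    n_levels: int
    levels: np.ndarray              # original level values, ascending
    distr: str = "logit"
    converged: bool = True
    loglike: float = np.nan

    def linear_predictor(self, X) -> np.ndarray:
        if self.coefficients.size == 0:
            return np.zeros(np.asarray(X).shape[0] if X is not None else 0)
        return np.asarray(X, dtype=float) @ self.coefficients

    def _cdf(self, z):
        return expit(z) if self.distr == "logit" else ndtr(z)

    def cumulative_probs(self, X) -> np.ndarray:
        """P(Y <= level_j | x) for j = 1..J (last column all ones)."""
        eta = self.linear_predictor(X)
        cum = self._cdf(self.thresholds[None, :] - eta[:, None])
        return np.column_stack([cum, np.ones_like(eta)])

    def level_probs(self, X) -> np.ndarray:
        cum = self.cumulative_probs(X)
        return np.diff(np.column_stack([np.zeros(cum.shape[0]), cum]), axis=1)


@dataclass
class CStatResult:
    c_apparent: float
    optimism: float
    c_corrected: float
    n_boot: int
    seed: int
    n_used: int = 0
    n_skipped: int = 0
    outcome: str | None = None
    timepoint_label: str | None = None


def fit_propodds(X, y, distr: str = "logit") -> OrdinalFit:
    """Maximum-likelihood cumulative-link fit.

    Rows with missing y must be excluded beforehand.  Levels absent from y
    are collapsed (the model is fit on the observed levels only).  An
    intercept-only model (X None or zero columns) is solved in closed form:
    thresholds are the empirical cumulative logits/probits.
    """
    y = np.asarray(y)
    obs_levels = np.unique(y)
    J = obs_levels.size
    if J < 2:
        raise ValueError("need at least 2 observed outcome levels")
    codes = np.searchsorted(obs_levels, y)

    p = 0
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p = X.shape[1]

    if p == 0:
        # intercept-only MLE: thresholds at empirical cumulative quantile
        # transforms
        cum = np.cumsum(np.bincount(codes, minlength=J))[:-1] / y.size
        inv = logit if distr == "logit" else _probit_inv
        return OrdinalFit(thresholds=inv(cum), coefficients=np.empty(0),
                          n_levels=J, levels=obs_levels, distr=distr,
                          converged=True)

    model = OrderedModel(codes, X, distr=distr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", disp=False, maxiter=500)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged:
            res = model.fit(method="lbfgs", disp=False, maxiter=2000)
            converged = bool(res.mle_retvals.get("converged", False))
    grad = model.score(res.params)
    if not np.all(np.isfinite(grad)) or np.linalg.norm(grad) > 1e-2 * y.size:
        converged = False
        log.warning("proportional-odds fit did not converge "
                    "(possible complete separation)")
    beta = np.asarray(res.params[:p], dtype=float)
    thresholds = np.asarray(
        model.transform_threshold_params(res.params)[1:-1], dtype=float)
    return OrdinalFit(thresholds=thresholds, coefficients=beta,
                      n_levels=J, levels=obs_levels, distr=distr,
                      converged=converged, loglike=float(res.llf))


def _probit_inv(q):
    from scipy.special import ndtri
    return ndtri(q)


def c_statistic(scores, y) -> float:
    """Generalized c-statistic over all pairs with different levels.

    Computed level-pair-wise from rank sums (Mann-Whitney U), equivalent
    to enumerating all comparable pairs with score ties counted 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and y must have equal length")
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("all outcome levels identical: c undefined")
    num = 0.0
    den = 0.0
    groups = [scores[y == lv] for lv in levels]
    for a in range(levels.size):
        for b in range(a + 1, levels.size):
            sa, sb = groups[a], groups[b]
            r = rankdata(np.concatenate([sa, sb]))
            u = r[sa.size:].sum() - sb.size * (sb.size + 1) / 2.0
            num += u
            den += sa.size * sb.size
    return num / den


def bootstrap_corrected_c(X, y, n_boot: int = 40, seed: int = 0,
                          outcome=None, timepoint_label=None) -> CStatResult:
    """Harrell's optimism bootstrap for the c-statistic.

    For each resample (with replacement, size n): refit the model, compute
    optimism_b = c(model_b on the resample) - c(model_b on the original
    data); the corrected c is the apparent c minus the mean optimism.
    Resamples missing an outcome level (or on which the fit fails) are
    redrawn, up to 100 redraws per repetition; a repetition still unusable
    after that is skipped with a log entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    full = fit_propodds(X, y)
    if not full.converged:
        raise RuntimeError("full-data proportional-odds fit did not converge")
    levels = full.levels
    c_app = c_statistic(full.linear_predictor(X), y)

    rng = np.random.default_rng(seed)
    optimisms = []
    n_skipped = 0
    for b in range(n_boot):
        fit_b = None
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.unique(yb).size != levels.size:
                continue
            try:
                cand = fit_propodds(X[idx], yb)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if cand.converged:
                fit_b = cand
                Xb, ybk = X[idx], yb
                break
        if fit_b is None:
            n_skipped += 1
            log.info("bootstrap repetition %d skipped after 100 redraws", b)
            continue
        c_boot = c_statistic(fit_b.linear_predictor(Xb), ybk)
        c_orig = c_statistic(fit_b.linear_predictor(X), y)
        optimisms.append(c_boot - c_orig)
    if len(optimisms) < 10:
        raise RuntimeError(
            f"only {len(optimisms)} usable bootstrap repetitions")
    optimism = float(np.mean(optimisms))
    return CStatResult(c_apparent=float(c_app), optimism=optimism,
                       c_corrected=float(c_app - optimism),
                       n_boot=n_boot, seed=seed, n_used=len(optimisms),
                       n_skipped=n_skipped, outcome=outcome,
                       timepoint_label=timepoint_label)
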