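"""Priority-weighted composite outcomes with prediction intervals.

A parent (or the autistic person themselves) allocates up to 100 priority
points across 10 facets of the adult outcome; a facet-to-outcome map turns
the points into non-negative weights over the K outcome measures.  The
composite is the weighted sum of the standardized, orientation-aligned
outcomes (ordinal outcomes contribute on the unit-variance latent scale of
a probit model).

Prediction intervals for a new individual need the joint residual
structure: all outcomes are modeled jointly on an identical predictor set,
and the K x K residual correlation matrix is assembled from pairwise
Pearson (continuous-continuous), polyserial (continuous-ordinal) and
polychoric (ordinal-ordinal) correlations, then projected to the nearest
positive-semidefinite correlation matrix if needed.  With identical
regressors across outcomes, the per-outcome coefficient estimates coincide
with the joint weighted-least-squares solution, so this two-stage route
reproduces the one-step joint fit.

For weights w, a new predictor vector x (augmented with the intercept) and
training Gram inverse G = (X'X)^{-1}:

    point   = sum_k w_k * (x' b_k)
    se^2    = (1 + x' G x) * (w' S w),   S = D^{1/2} R D^{1/2}

where D holds the per-outcome residual variances (1 on the ordinal latent
scale) and R the residual correlations.  The (1 + x'Gx) factor carries
parameter-estimation uncertainty; w'Sw carries residual uncertainty, and
weak residual correlation is exactly what makes composite intervals
narrower than single-outcome intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import pearsonr

from .ordinal import fit_propodds
from .preprocess import standardize_outcomes, StandardizeTransform
from .synthetic import FACET_LABELS, CohortTable

__all__ = [
    "PriorityProfile",
    "FacetOutcomeMap",
    "JointOutcomeModel",
    "CompositePrediction",
    "default_facet_map",
    "map_priorities_to_weights",
    "fit_joint_model",
    "predict_outcome_interval",
    "predict_composite_interval",
    "bvn_cdf",
    "nearest_psd_correlation",
]


@dataclass
class PriorityProfile:
    """Elicited priority points: up to 100 spread over 10 facets."""

    facet_points: np.ndarray
    labels: list = field(default_factory=lambda: list(FACET_LABELS))

    def __post_init__(self):
        self.facet_points = np.asarray(self.facet_points, dtype=float)
        if self.facet_points.size != len(self.labels):
            raise ValueError("one point value per facet label required")
        if np.any(self.facet_points < 0):
            raise ValueError("facet points must be non-negative")
        if self.facet_points.sum() > 100 + 1e-9:
            raise ValueError("facet points may total at most 100")


@dataclass
class FacetOutcomeMap:
    """Row-stochastic 10 x K map distributing each facet over outcomes."""

    matrix: np.ndarray
    facet_labels: list
    outcome_names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.facet_labels),
                                 len(self.outcome_names)):
            raise ValueError("matrix shape must be n_facets x n_outcomes")
        if np.any(self.matrix < 0):
            raise ValueError("facet-outcome shares must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("each facet row must sum to 1")


#: which outcomes each facet maps onto, split uniformly
_DEFAULT_FACET_OUTCOMES = {
    "independence": ["independent_living"],
    "work": ["sef_work"],
    "friendships": ["sef_friends"],
    "autism_symptoms": ["adult_css"],
    "behavior_problems": ["adult_abcl", "adult_irritability",
                          "adult_hyperactivity"],
    "emotional_wellbeing": ["adult_wbq"],
    "depression": ["adult_bdi"],
    "positive_emotions": ["adult_panas_p", "adult_panas_n"],
    "cognitive_ability": ["adult_viq", "adult_nviq"],
    "daily_living_skills": ["adult_dls"],
}


def default_facet_map(outcome_names: list) -> FacetOutcomeMap:
    M = np.zeros((len(FACET_LABELS), len(outcome_names)))
    idx = {o: j for j, o in enumerate(outcome_names)}
    for i, facet in enumerate(FACET_LABELS):
        targets = [o for o in _DEFAULT_FACET_OUTCOMES[facet] if o in idx]
        if not targets:
            raise ValueError(f"no outcome available for facet {facet!r}")
        for o in targets:
            M[i, idx[o]] = 1.0 / len(targets)
    return FacetOutcomeMap(M, list(FACET_LABELS), list(outcome_names))


def map_priorities_to_weights(profile: PriorityProfile,
                              fmap: FacetOutcomeMap) -> pd.Series:
    """w = (points / 100)' M; sums to total points / 100 (<= 1)."""
    if list(profile.labels) != list(fmap.facet_labels):
        raise ValueError("profile and map facet labels disagree")
    w = (profile.facet_points / 100.0) @ fmap.matrix
    return pd.Series(w, index=fmap.outcome_names)


# ---------------------------------------------------------------------------
# bivariate normal rectangle probabilities (for polychoric likelihoods)
# ---------------------------------------------------------------------------

# Gauss-Legendre nodes/weights on (-1, 1), from Genz's BVND
_GL = {
    6: (np.array([0.9324695142031522, 0.6612093864662647,
                  0.2386191860831970]),
        np.array([0.1713244923791705, 0.3607615730481384,
                  0.4679139345726904])),
    12: (np.array([0.9815606342467191, 0.9041172563704750,
                   0.7699026741943050, 0.5873179542866171,
                   0.3678314989981802, 0.1252334085114692]),
         np.array([0.04717533638651177, 0.1069393259953183,
                   0.1600783285433464, 0.2031674267230659,
                   0.2334925365383547, 0.2491470458134029])),
    20: (np.array([0.9931285991850949, 0.9639719272779138,
                   0.9122344282513259, 0.8391169718222188,
                   0.7463319064601508, 0.6360536807265150,
                   0.5108670019508271, 0.3737060887154196,
                   0.2277858511416451, 0.07652652113349733]),
         np.array([0.01761400713915212, 0.04060142980038694,
                   0.06267204833410906, 0.08327674157670475,
                   0.1019301198172404, 0.1181945319615184,
                   0.1316886384491766, 0.1420961093183821,
                   0.1491729864726037, 0.1527533871307259])),
}


def _bvnu(h, k, r: float):
    """P(X > h, Y > k) for standard bivariate normal, vectorized in h, k.

    Genz's adaptation of the Drezner-Wesolowsky algorithm; absolute
    accuracy ~5e-16 for |r| < 0.925 and ~5e-9 beyond.
    """
    # clamp to +-8: the neglected tail mass is below 1e-15, and infinite
    # bounds (open-ended ordinal categories) become well-defined
    h = np.clip(np.asarray(h, dtype=float), -8.0, 8.0)
    k = np.clip(np.asarray(k, dtype=float), -8.0, 8.0)
    h, k = np.broadcast_arrays(h, k)
    if r == 0.0:
        return ndtr(-h) * ndtr(-k)
    ar = abs(r)
    npts = 6 if ar < 0.3 else (12 if ar < 0.75 else 20)
    xs, ws = _GL[npts]
    # symmetric nodes
    xn = np.concatenate([-xs, xs])
    wn = np.concatenate([ws, ws])

    hk = h * k
    if ar < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = np.arcsin(r)
        sn = np.sin(asr * (xn + 1.0) / 2.0)      # (2m,)
        f = np.exp((sn[:, None] * hk.ravel()[None, :] - hs.ravel()[None, :])
                   / (1.0 - sn[:, None] ** 2))
        bvn = (wn @ f) * asr / (4.0 * np.pi)
        bvn = bvn.reshape(h.shape) + ndtr(-h) * ndtr(-k)
        return np.clip(bvn, 0.0, 1.0)

    # |r| >= 0.925: Genz tail expansion
    twopi = 2.0 * np.pi
    if r < 0.0:
        k = -k
        hk = -hk
    bvn = np.zeros(h.shape).ravel()
    hf = h.ravel()
    kf = k.ravel()
    hkf = hk.ravel()
    if ar < 1.0:
        as_ = (1.0 - r) * (1.0 + r)
        a = np.sqrt(as_)
        bs = (hf - kf) ** 2
        c = (4.0 - hkf) / 8.0
        d = (12.0 - hkf) / 16.0
        asr = -(bs / as_ + hkf) / 2.0
        mask = asr > -100.0
        bvn[mask] = (a * np.exp(asr[mask])
                     * (1.0 - c[mask] * (bs[mask] - as_)
                        * (1.0 - d[mask] * bs[mask] / 5.0) / 3.0
                        + c[mask] * d[mask] * as_ * as_ / 5.0))
        mask2 = -hkf < 100.0
        b = np.sqrt(bs)
        bvn[mask2] -= (np.exp(-hkf[mask2] / 2.0) * np.sqrt(twopi)
                       * ndtr(-b[mask2] / a) * b[mask2]
                       * (1.0 - c[mask2] * bs[mask2]
                          * (1.0 - d[mask2] * bs[mask2] / 5.0) / 3.0))
        a /= 2.0
        for i in range(len(xn)):
            xsq = (a * (xn[i] + 1.0)) ** 2
            rs = np.sqrt(1.0 - xsq)
            asr2 = -(bs / xsq + hkf) / 2.0
            m = asr2 > -100.0
            bvn[m] += (a * wn[i] * np.exp(asr2[m])
                       * (np.exp(-hkf[m] * (1.0 - rs) / (2.0 * (1.0 + rs)))
                          / rs
                          - (1.0 + c[m] * xsq * (1.0 + d[m] * xsq))))
        bvn = -bvn / twopi
    if r > 0.0:
        bvn = bvn + ndtr(-np.maximum(hf, kf))
    else:
        bvn = -bvn
        diff = ndtr(kf) - ndtr(hf)
        bvn = bvn + np.maximum(0.0, diff)
    return np.clip(bvn.reshape(h.shape), 0.0, 1.0)


def bvn_cdf(x, y, rho: float):
    """P(X <= x, Y <= y) for standard bivariate normal with correlation rho."""
    return _bvnu(-np.asarray(x, dtype=float), -np.asarray(y, dtype=float),
                 float(rho))


# ---------------------------------------------------------------------------
# latent correlation estimators
# ---------------------------------------------------------------------------

_RHO_BOUND = 0.999


def _polyserial_mle(z, lo, hi) -> float:
    """MLE latent correlation between a unit-variance continuous residual z
    and an ordinal variable whose latent residual lies in (lo, hi]."""
    z = np.asarray(z, dtype=float)

    def negll(rho):
        s = np.sqrt(1.0 - rho * rho)
        p = ndtr((hi - rho * z) / s) - ndtr((lo - rho * z) / s)
        return -np.sum(np.log(np.clip(p, 1e-300, None)))

    res = minimize_scalar(negll, bounds=(-_RHO_BOUND, _RHO_BOUND),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def _polychoric_mle(lo1, hi1, lo2, hi2) -> float:
    """MLE latent correlation between two ordinal variables with latent
    residuals in (lo1, hi1] x (lo2, hi2] per row."""

    def negll(rho):
        p = (_bvnu(lo1, lo2, rho) - _bvnu(lo1, hi2, rho)
             - _bvnu(hi1, lo2, rho) + _bvnu(hi1, hi2, rho))
        return -np.sum(np.log(np.clip(p, 1e-300, None)))

    res = minimize_scalar(negll, bounds=(-_RHO_BOUND, _RHO_BOUND),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-10):
    """Eigenvalue-clipped nearest PSD correlation; returns (R_psd, distance)."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= 0.0:
        return R, 0.0
    w = np.clip(w, eps, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A, float(np.linalg.norm(R - A, "fro"))


# ---------------------------------------------------------------------------
# the joint outcome model
# ---------------------------------------------------------------------------

@dataclass
class JointOutcomeModel:
    outcome_names: list
    kinds: dict                    # outcome -> "continuous" | "ordinal"
    coefficients: dict             # outcome -> (intercept, beta vector)
    thresholds: dict               # ordinal outcome -> increasing array
    resid_sd: dict                 # outcome -> residual SD (1 for ordinal)
    R: np.ndarray                  # K x K residual correlation (PSD)
    R_raw: np.ndarray
    psd_adjustment: float
    G: np.ndarray                  # (p+1) x (p+1) Gram inverse, with intercept
    predictor_columns: list
    transform: StandardizeTransform
    n_used: int = 0
    nonconverged: list = field(default_factory=list)

    def residual_covariance(self) -> np.ndarray:
        s = np.array([self.resid_sd[o] for o in self.outcome_names])
        return self.R * np.outer(s, s)

    def point(self, x_new: np.ndarray, outcome: str) -> float:
        b0, beta = self.coefficients[outcome]
        return float(b0 + np.asarray(x_new, dtype=float) @ beta)


@dataclass
class CompositePrediction:
    point: float
    se_pred: float
    interval: tuple
    level: float = 0.95
    weights: pd.Series | None = None
    outcome: str | None = None
    thresholds: np.ndarray | None = None


def fit_joint_model(table: CohortTable, predictor_columns: list,
                    continuous_outcomes: list, ordinal_outcomes: list,
                    orientation_map: dict) -> JointOutcomeModel:
    """Joint model of all outcomes on an identical predictor set.

    The table must have complete predictors and KNN-imputed outcomes.
    Continuous outcomes are standardized and oriented (so higher always
    means a less severe impact by default); ordinal outcomes are fit by
    probit regression on their (orientation-aligned) level order, putting
    them on a unit-variance latent scale.  Residual correlations are
    estimated pairwise (Pearson / polyserial / polychoric) and the
    assembled matrix is projected to the nearest PSD correlation matrix,
    with the projection distance recorded.
    """
    df = table.data
    X = df[list(predictor_columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("predictors must be complete (impute first)")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("fewer rows than predictors + intercept")
    Xa = np.column_stack([np.ones(n), X])
    G = np.linalg.inv(Xa.T @ Xa)

    cont_map = {o: orientation_map[o] for o in continuous_outcomes}
    std_table, tf = standardize_outcomes(table, cont_map)

    names = list(continuous_outcomes) + list(ordinal_outcomes)
    kinds = {o: "continuous" for o in continuous_outcomes}
    kinds.update({o: "ordinal" for o in ordinal_outcomes})
    coefs, thresholds, resid_sd = {}, {}, {}
    nonconverged = []

    # per-outcome fits and residual summaries
    zresid = {}            # continuous: unit-variance residuals
    bounds = {}            # ordinal: (lo, hi) latent-residual intervals
    for o in continuous_outcomes:
        y = std_table.data[o].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"outcome {o!r} has missing values; impute "
                             f"outcomes before joint modeling")
        coef, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        resid = y - Xa @ coef
        dof = max(n - p - 1, 1)
        s = float(np.sqrt(resid @ resid / dof))
        coefs[o] = (float(coef[0]), coef[1:])
        resid_sd[o] = s
        zresid[o] = resid / s if s > 0 else resid

    for o in ordinal_outcomes:
        y = df[o].to_numpy()
        if np.isnan(np.asarray(y, dtype=float)).any():
            raise ValueError(f"outcome {o!r} has missing values; impute "
                             f"outcomes before joint modeling")
        sign = float(orientation_map[o])
        yy = y if sign > 0 else -np.asarray(y, dtype=float)
        fit = fit_propodds(X, yy, distr="probit")
        if not fit.converged:
            nonconverged.append(o)
        eta = fit.linear_predictor(X)
        # centre the latent scale at the cohort mean so ordinal components
        # are mean-zero like the standardized continuous ones; shifting
        # the thresholds by the same amount leaves all probabilities
        # unchanged
        m = float(eta.mean())
        coefs[o] = (-m, fit.coefficients)
        thresholds[o] = fit.thresholds - m
        resid_sd[o] = 1.0
        codes = np.searchsorted(fit.levels, yy)
        edges = np.concatenate([[-np.inf], fit.thresholds, [np.inf]])
        bounds[o] = (edges[codes] - eta, edges[codes + 1] - eta)

    K = len(names)
    R_raw = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            oi, oj = names[i], names[j]
            ki, kj = kinds[oi], kinds[oj]
            if ki == "continuous" and kj == "continuous":
                r = float(pearsonr(zresid[oi], zresid[oj])[0])
            elif ki == "continuous":
                r = _polyserial_mle(zresid[oi], *bounds[oj])
            elif kj == "continuous":
                r = _polyserial_mle(zresid[oj], *bounds[oi])
            else:
                r = _polychoric_mle(*bounds[oi], *bounds[oj])
            R_raw[i, j] = R_raw[j, i] = r
    R, dist = nearest_psd_correlation(R_raw)

    return JointOutcomeModel(
        outcome_names=names, kinds=kinds, coefficients=coefs,
        thresholds=thresholds, resid_sd=resid_sd, R=R, R_raw=R_raw,
        psd_adjustment=dist, G=G, predictor_columns=list(predictor_columns),
        transform=tf, n_used=n, nonconverged=nonconverged)


def _leverage(model: JointOutcomeModel, x_new) -> float:
    xa = np.concatenate([[1.0], np.asarray(x_new, dtype=float)])
    if xa.size != model.G.shape[0]:
        raise ValueError("x_new not conformable with the training design")
    return float(xa @ model.G @ xa)


def predict_outcome_interval(model: JointOutcomeModel, x_new, outcome: str,
                             level: float = 0.95) -> CompositePrediction:
    """Point prediction and prediction interval for a single outcome.

    Continuous outcomes are on the standardized, oriented scale; ordinal
    outcomes on the unit-variance latent probit scale, with the threshold
    positions attached for interpretation.
    """
    if outcome not in model.kinds:
        raise KeyError(f"unknown outcome {outcome!r}")
    point = model.point(x_new, outcome)
    s2 = model.resid_sd[outcome] ** 2
    se = float(np.sqrt(s2 * (1.0 + _leverage(model, x_new))))
    z = ndtri((1.0 + level) / 2.0)
    return CompositePrediction(
        point=point, se_pred=se, interval=(point - z * se, point + z * se),
        level=level, outcome=outcome,
        thresholds=model.thresholds.get(outcome))


def predict_composite_interval(model: JointOutcomeModel, x_new, w,
                               level: float = 0.95) -> CompositePrediction:
    """Point prediction and prediction interval for a weighted composite."""
    if isinstance(w, pd.Series):
        w = w.reindex(model.outcome_names).fillna(0.0)
        wv = w.to_numpy(dtype=float)
    else:
        wv = np.asarray(w, dtype=float)
        if wv.size != len(model.outcome_names):
            raise ValueError("weight vector length must equal the number "
                             "of outcomes")
        w = pd.Series(wv, index=model.outcome_names)
    if np.any(wv < 0):
        raise ValueError("weights must be non-negative")
    if np.all(wv == 0):
        raise ValueError("all-zero weight vector")
    points = np.array([model.point(x_new, o) for o in model.outcome_names])
    point = float(wv @ points)
    S = model.residual_covariance()
    se = float(np.sqrt((1.0 + _leverage(model, x_new)) * (wv @ S @ wv)))
    z = ndtri((1.0 + level) / 2.0)
    return CompositePrediction(
        point=point, se_pred=se, interval=(point - z * se, point + z * se),
        level=level, weights=w)
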