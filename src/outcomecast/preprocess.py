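"""Scale pro-rating, predictor-set assembly, KNN imputation, standardization.

Predictor sets follow the most-recent-measurement rule: demographics enter
at every model timepoint; the childhood core measures (IQ, symptom
severity, daily-living skills, diagnosis) enter at their own age up to 9
and are frozen at their age-9 values afterwards; each adolescent
behavioural measure is represented only by its most recent assessment.
The starred labels 14* and 17* add the two teacher-reported SDQ subscales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .synthetic import DEMOGRAPHICS, CohortTable

__all__ = [
    "ScaleItems",
    "PredictorSetSpec",
    "AnalysisMatrix",
    "StandardizeTransform",
    "TIMEPOINT_LABELS",
    "default_predictor_sets",
    "prorate_scale",
    "assemble_predictors",
    "knn_impute",
    "standardize_outcomes",
]

TIMEPOINT_LABELS = ["2", "3", "5", "9", "14", "14*", "15", "17", "17*"]


@dataclass
class ScaleItems:
    item_values: np.ndarray
    n_items: int

    def __post_init__(self):
        self.item_values = np.asarray(self.item_values, dtype=float)
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.item_values.size != self.n_items:
            raise ValueError("length of item_values must equal n_items")


def prorate_scale(items: ScaleItems, min_complete: float = 0.8):
    """Pro-rate a partially completed scale.

    If at least ``min_complete`` of items were answered, the scale total is
    estimated as mean(answered) * n_items; otherwise the scale is missing.
    """
    vals = items.item_values
    answered = ~np.isnan(vals)
    frac = answered.sum() / items.n_items
    if frac < min_complete:
        return np.nan
    return float(np.nanmean(vals) * items.n_items)


@dataclass
class PredictorSetSpec:
    timepoint_label: str
    columns: list
    includes_sdq: bool = False

    def __post_init__(self):
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate predictor columns")
        for d in DEMOGRAPHICS:
            if d not in self.columns:
                raise ValueError(f"demographic {d!r} missing from predictor "
                                 f"set {self.timepoint_label}")


@dataclass
class AnalysisMatrix:
    row_ids: np.ndarray
    X: pd.DataFrame
    y: pd.Series | None
    timepoint_label: str
    outcome: str | None = None


def _core(age) -> list:
    return [f"viq_{age}", f"nviq_{age}", f"css_{age}", f"dls_{age}",
            f"asd_dx_{age}"]


def default_predictor_sets() -> dict:
    """The nine model timepoints and their predictor columns."""
    sets = {}
    for age in (2, 3, 5):
        sets[str(age)] = PredictorSetSpec(
            str(age), DEMOGRAPHICS + _core(age))
    sets["9"] = PredictorSetSpec(
        "9", DEMOGRAPHICS + _core(9)
        + ["irritability_9", "hyperactivity_9", "cbcl_9"])
    base14 = (DEMOGRAPHICS + _core(9)
              + ["irritability_14", "hyperactivity_14", "cbcl_9"])
    sets["14"] = PredictorSetSpec("14", list(base14))
    sets["14*"] = PredictorSetSpec(
        "14*", base14 + ["sdq_emotion_14", "sdq_prosocial_14"],
        includes_sdq=True)
    sets["15"] = PredictorSetSpec(
        "15", DEMOGRAPHICS + _core(9)
        + ["irritability_14", "hyperactivity_14", "cbcl_15"])
    base17 = (DEMOGRAPHICS + _core(9)
              + ["irritability_17", "hyperactivity_17", "cbcl_15"])
    sets["17"] = PredictorSetSpec("17", list(base17))
    sets["17*"] = PredictorSetSpec(
        "17*", base17 + ["sdq_emotion_17", "sdq_prosocial_17"],
        includes_sdq=True)
    return sets


def assemble_predictors(table: CohortTable, spec: PredictorSetSpec,
                        outcome: str | None = None) -> AnalysisMatrix:
    """Select exactly the spec's predictor columns (pre-imputation)."""
    df = table.data
    missing = [c for c in spec.columns if c not in df.columns]
    if missing:
        raise KeyError(f"predictor column(s) not in table: {missing}")
    y = None
    if outcome is not None:
        if outcome not in df.columns:
            raise KeyError(f"outcome column not in table: {outcome!r}")
        y = df[outcome]
    return AnalysisMatrix(row_ids=df.index.to_numpy(),
                          X=df[spec.columns].copy(), y=y,
                          timepoint_label=spec.timepoint_label,
                          outcome=outcome)


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def _is_discrete(col: pd.Series, max_levels: int = 10) -> bool:
    vals = col.dropna().to_numpy()
    if vals.size == 0:
        return False
    if not np.allclose(vals, np.round(vals)):
        return False
    # level-like: few unique integer values spanning a narrow range
    return (np.unique(vals).size <= max_levels
            and vals.max() - vals.min() <= max_levels)


def knn_impute(table: CohortTable, k: int = 5,
               columns: list | None = None,
               discrete: list | None = None) -> CohortTable:
    """Fill missing cells by k-nearest-neighbour imputation.

    Distance between rows is Euclidean over the coordinates both rows have
    observed, computed on column-standardized values and rescaled by the
    ratio of total to shared observed coordinates (so rows with little
    overlap are not spuriously close).  Continuous cells take the mean of
    the k nearest rows observed for that column; discrete (binary/ordinal)
    cells take their mode, ties resolved to the lowest value.  Distance
    ties are broken by row order, making the result deterministic.

    Imputation is intended to run on the whole dataset before any
    validation split.
    """
    df = table.data.copy()
    cols = list(columns) if columns is not None else [
        c for c in df.columns if df[c].isna().any()]
    if not cols:
        return CohortTable(data=df, ground_truth=dict(table.ground_truth),
                           config=table.config)
    if discrete is None:
        discrete = [c for c in df.columns if _is_discrete(df[c])]
    discrete = set(discrete)

    # distances on all numeric columns, standardized (population SD)
    num = df.select_dtypes(include=[np.number])
    mu = num.mean()
    sd = num.std(ddof=0).replace(0.0, 1.0)
    Z = ((num - mu) / sd).to_numpy()
    with np.errstate(invalid="ignore"):
        D = nan_euclidean_distances(Z, Z)
    np.fill_diagonal(D, np.inf)
    D = np.where(np.isnan(D), np.inf, D)

    imputed_flags = pd.DataFrame(False, index=df.index, columns=cols)
    order = np.argsort(D, axis=1, kind="stable")  # row-order tie-break
    for col in cols:
        y = df[col].to_numpy(dtype=float)
        observed = ~np.isnan(y)
        if observed.sum() == 0:
            raise ValueError(f"column {col!r} has no observed values to "
                             f"impute from")
        if observed.sum() < k:
            raise ValueError(f"column {col!r} has fewer than k={k} observed "
                             f"values")
        for i in np.flatnonzero(~observed):
            cand = order[i][observed[order[i]] & np.isfinite(D[i, order[i]])]
            neigh = y[cand[:k]]
            if col in discrete:
                vals, counts = np.unique(neigh, return_counts=True)
                fill = vals[np.argmax(counts)]  # lowest value on count tie
            else:
                fill = neigh.mean()
            y[i] = fill
            imputed_flags.loc[df.index[i], col] = True
        df[col] = y

    truth = dict(table.ground_truth)
    truth["imputed_flags"] = imputed_flags
    return CohortTable(data=df, ground_truth=truth, config=table.config)


# ---------------------------------------------------------------------------
# outcome standardization and orientation
# ---------------------------------------------------------------------------

@dataclass
class StandardizeTransform:
    """Per-outcome (mean, sd, sign); sample-SD convention (divisor n - 1)."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    signs: dict = field(default_factory=dict)

    def apply(self, values, outcome: str):
        return self.signs[outcome] * (
            (np.asarray(values, dtype=float) - self.means[outcome])
            / self.sds[outcome])

    def invert(self, z, outcome: str):
        return (np.asarray(z, dtype=float) / self.signs[outcome]
                * self.sds[outcome] + self.means[outcome])


def standardize_outcomes(table: CohortTable, orientation_map: dict,
                         outcomes: list | None = None):
    """Standardize outcomes to mean 0 / variance 1 and orient them.

    ``orientation_map`` gives the sign s_k in {+1, -1} per outcome; with
    the default figure convention, signs are chosen so that higher
    standardized scores indicate a less severe impact.  Returns the
    transformed table and the :class:`StandardizeTransform` for inversion.
    Missing values stay missing.
    """
    df = table.data.copy()
    outcomes = list(orientation_map) if outcomes is None else list(outcomes)
    tf = StandardizeTransform()
    for out in outcomes:
        s = float(orientation_map[out])
        if s not in (1.0, -1.0):
            raise ValueError(f"orientation sign for {out!r} must be +/-1")
        vals = df[out].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size < 2:
            raise ValueError(f"outcome {out!r} has fewer than 2 observed "
                             f"values")
        m, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"outcome {out!r} has zero variance")
        tf.means[out], tf.sds[out], tf.signs[out] = m, sd, s
        df[out] = s * (vals - m) / sd
    return CohortTable(data=df, ground_truth=dict(table.ground_truth),
                       config=table.config), tf
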