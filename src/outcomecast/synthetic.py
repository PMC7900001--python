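"""Seeded synthetic cohorts with known ground truth.

The real developmental cohorts used to build long-range outcome prediction
models contain sensitive clinical data and cannot be shared, so every stage
of this package is exercised on synthetic cohorts instead.  The generator
emulates the statistical structure such an analysis assumes:

* repeated childhood measures (verbal/non-verbal IQ, autism symptom
  severity, daily-living skills) at ages 2, 3, 5 and 9, plus adolescent
  behavioural measures (irritability, hyperactivity, CBCL total, SDQ
  subscales), built from a shared per-measure trait so that later
  measurements of a construct predict its adult analogue more strongly
  than earlier ones (an AR(1)-like loading schedule);
* adult outcomes that are linear in the (standardized) generative
  predictors with multivariate-normal residuals — continuous outcomes on a
  configurable location/scale, ordinal outcomes by thresholding a
  unit-variance latent normal that shares the residual correlation;
* missingness that is associated with race and maternal education
  (whole-wave dropout from a logistic model) on top of item-level blanking.

Because the generative model is exactly the model the downstream analysis
assumes (linear-Gaussian continuous outcomes, probit-latent ordinal
outcomes), recovery tests against the recorded ground truth are sharp.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

__all__ = [
    "MeasureSpec",
    "OutcomeSpec",
    "MissingnessSpec",
    "CohortConfig",
    "CohortTable",
    "DEMOGRAPHICS",
    "FACET_LABELS",
    "default_measures",
    "default_outcomes",
    "default_config",
    "generate_cohort",
    "population_r2",
    "apply_missingness",
    "generate_priority_profile",
    "default_orientation_map",
]

DEMOGRAPHICS = ["female", "non_caucasian", "maternal_edu"]

#: The ten facets of the adult outcome over which priority points are spread.
FACET_LABELS = [
    "independence",
    "work",
    "friendships",
    "autism_symptoms",
    "behavior_problems",
    "emotional_wellbeing",
    "depression",
    "positive_emotions",
    "cognitive_ability",
    "daily_living_skills",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class MeasureSpec:
    """A repeated childhood/adolescent measure.

    The value at age ``t`` is ``mean[t] + sd * (loading[t] * trait +
    sqrt(1 - loading[t]^2) * noise)`` where ``trait`` is a unit-normal
    per-participant, per-measure factor.  Loadings increase with age so
    that the most recent measurement is the best proxy for the trait.
    """

    name: str
    ages: tuple
    means: dict
    sd: float
    loadings: dict  # age -> trait loading in [0, 1]

    def column(self, age) -> str:
        return f"{self.name}_{age}"

    def validate(self) -> None:
        for a in self.ages:
            lam = self.loadings[a]
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"loading for {self.name} at age {a} "
                                 f"must be in [0, 1], got {lam}")
        if self.sd <= 0:
            raise ValueError(f"sd for {self.name} must be positive")


@dataclass
class OutcomeSpec:
    """One adult outcome and its generative model.

    ``loadings`` are coefficients on *standardized* generative predictor
    columns (measure columns are standardized by their configured mean/sd).
    Continuous outcomes are reported as ``mean + scale * (eta + resid)``
    with ``resid ~ N(0, residual_sd^2)``; ordinal outcomes threshold the
    unit-variance latent ``eta + resid``.
    """

    name: str
    kind: str = "continuous"  # "continuous" | "ordinal"
    orientation: str = "higher_less_severe"
    loadings: dict = field(default_factory=dict)
    residual_sd: float = 1.0
    n_levels: int = 0
    thresholds: tuple = ()
    level_values: tuple = ()
    mean: float = 0.0
    scale: float = 1.0
    range_clip: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.orientation not in ("higher_less_severe", "higher_more_severe"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.kind == "ordinal":
            if self.n_levels < 2:
                raise ValueError("ordinal outcomes need n_levels >= 2")
            if len(self.thresholds) != self.n_levels - 1:
                raise ValueError("need n_levels - 1 thresholds")
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValueError("thresholds must be strictly increasing")
            if not self.level_values:
                self.level_values = tuple(range(1, self.n_levels + 1))
            # latent residual is fixed at unit variance
            self.residual_sd = 1.0
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")

    @property
    def sign(self) -> float:
        """+1 if higher scores already mean a less severe impact."""
        return 1.0 if self.orientation == "higher_less_severe" else -1.0


@dataclass
class MissingnessSpec:
    """Item-level blanking plus MAR whole-wave dropout.

    Dropout probability per participant is
    ``logistic(intercept + b_race * non_caucasian + b_edu * (maternal_edu - 3))``;
    a dropped participant loses all measurement waves from a random
    post-baseline wave onward (monotone dropout).  Demographics are never
    blanked — the dropout mechanism conditions on them, which is what makes
    the missingness MAR rather than MNAR.
    """

    item_missing_prob: dict | float = 0.0
    mar_coefficients: dict = field(default_factory=lambda: {
        "intercept": -10.0, "non_caucasian": 0.0, "maternal_edu": 0.0})
    outcome_missing_prob: dict | float = 0.0

    def item_prob(self, col: str) -> float:
        if isinstance(self.item_missing_prob, dict):
            return float(self.item_missing_prob.get(col, 0.0))
        return float(self.item_missing_prob)

    def outcome_prob(self, col: str) -> float:
        if isinstance(self.outcome_missing_prob, dict):
            return float(self.outcome_missing_prob.get(col, 0.0))
        return float(self.outcome_missing_prob)

    def validate(self) -> None:
        probs = []
        for p in (self.item_missing_prob, self.outcome_missing_prob):
            probs.extend(p.values() if isinstance(p, dict) else [p])
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness probability {p} outside [0, 1]")


@dataclass
class CohortConfig:
    n_participants: int = 123
    seed: int = 0
    measures: list = field(default_factory=lambda: default_measures())
    outcome_specs: list = field(default_factory=lambda: default_outcomes())
    residual_correlation: np.ndarray | None = None  # K x K; None -> default
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    #: correlation between the traits of different measures (shared factor)
    trait_correlation: float = 0.5
    p_female: float = 0.17
    p_non_caucasian: float = 0.17
    maternal_edu_probs: tuple = (0.30, 0.30, 0.20, 0.15, 0.05)
    clip_outcomes: bool = False
    #: off-diagonal residual correlation used when residual_correlation is None
    default_residual_corr: float = 0.2

    def __post_init__(self):
        K = len(self.outcome_specs)
        if self.residual_correlation is None:
            R = np.full((K, K), self.default_residual_corr)
            np.fill_diagonal(R, 1.0)
            self.residual_correlation = R
        else:
            self.residual_correlation = np.asarray(
                self.residual_correlation, dtype=float)

    def validate(self) -> None:
        R = self.residual_correlation
        K = len(self.outcome_specs)
        if R.shape != (K, K):
            raise ValueError(f"residual_correlation must be {K}x{K}")
        if not np.allclose(R, R.T):
            raise ValueError("residual_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("residual_correlation must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("residual_correlation must be positive "
                             "semidefinite")
        if not 0.0 <= self.trait_correlation <= 1.0:
            raise ValueError("trait_correlation must be in [0, 1]")
        for m in self.measures:
            m.validate()
        self.missingness.validate()

    @property
    def outcome_names(self) -> list:
        return [s.name for s in self.outcome_specs]


@dataclass
class CohortTable:
    """One row per participant; all predictors and outcomes as columns.

    ``ground_truth`` keeps the generative parameters (true coefficients,
    population R² per outcome, residual correlation, linear predictors and,
    after :func:`apply_missingness`, the pre-missingness values) for
    recovery tests.  It travels with the table in memory; ``to_csv`` writes
    a JSON sidecar with the serializable part.
    """

    data: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)
    config: CohortConfig | None = None

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, na_rep="")
        sidecar = {}
        for key, val in self.ground_truth.items():
            if isinstance(val, np.ndarray):
                sidecar[key] = val.tolist()
            elif isinstance(val, (dict, list, str, int, float)):
                sidecar[key] = _jsonify(val)
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        data = pd.read_csv(path)
        truth = {}
        try:
            with open(str(path) + ".truth.json") as fh:
                truth = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(data=data, ground_truth=truth)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# defaults — the study conditions the generator emulates
# ---------------------------------------------------------------------------

_CORE_LOADINGS = {2: 0.60, 3: 0.70, 5: 0.80, 9: 0.90}
_BEHAV_LOADINGS = {9: 0.75, 14: 0.85, 17: 0.90}


def default_measures() -> list:
    """Repeated-measure specifications loosely calibrated to a referred-for-
    autism cohort: low and widely spread verbal IQ early on, severity scores
    centred high, Vineland daily-living standard scores in the 60s."""
    return [
        MeasureSpec("viq", (2, 3, 5, 9), {2: 40, 3: 44, 5: 48, 9: 55},
                    25.0, dict(_CORE_LOADINGS)),
        MeasureSpec("nviq", (2, 3, 5, 9), {2: 70, 3: 72, 5: 74, 9: 76},
                    25.0, dict(_CORE_LOADINGS)),
        MeasureSpec("css", (2, 3, 5, 9), {2: 6.5, 3: 6.5, 5: 6.3, 9: 6.0},
                    2.0, dict(_CORE_LOADINGS)),
        MeasureSpec("dls", (2, 3, 5, 9), {2: 68, 3: 68, 5: 67, 9: 65},
                    10.0, dict(_CORE_LOADINGS)),
        MeasureSpec("irritability", (9, 14, 17), {9: 7, 14: 6, 17: 6},
                    6.0, dict(_BEHAV_LOADINGS)),
        MeasureSpec("hyperactivity", (9, 14, 17), {9: 10, 14: 9, 17: 8},
                    7.0, dict(_BEHAV_LOADINGS)),
        MeasureSpec("cbcl", (9, 15), {9: 57, 15: 55}, 10.0,
                    {9: 0.80, 15: 0.90}),
        MeasureSpec("sdq_emotion", (14, 17), {14: 4, 17: 4}, 2.5,
                    {14: 0.85, 17: 0.90}),
        MeasureSpec("sdq_prosocial", (14, 17), {14: 5, 17: 5}, 2.5,
                    {14: 0.85, 17: 0.90}),
    ]


def default_outcomes() -> list:
    """Fourteen adult outcomes: 11 continuous, 3 ordinal (3, 4 and 7 levels,
    mirroring independent-living 1–3, friendship 0–3 and work 1–7 scales).

    Loadings are chosen to reproduce the qualitative predictability
    gradient such analyses report: cognitive/adaptive outcomes strongly
    predicted by their age-9 analogues, behavioural outcomes moderately
    predicted by adolescent measures, and well-being/affect/depression
    outcomes essentially unpredictable.
    """
    return [
        OutcomeSpec("adult_viq", loadings={"viq_9": 1.0}, residual_sd=0.37,
                    mean=60, scale=36, range_clip=(2, 139)),
        OutcomeSpec("adult_nviq", loadings={"nviq_9": 1.0}, residual_sd=0.44,
                    mean=70, scale=34, range_clip=(3, 133)),
        OutcomeSpec("adult_dls", loadings={"dls_9": 1.0}, residual_sd=0.60,
                    mean=60, scale=25, range_clip=(17, 112)),
        OutcomeSpec("adult_hyperactivity", orientation="higher_more_severe",
                    loadings={"hyperactivity_17": 0.70}, residual_sd=0.80,
                    mean=7, scale=6.5, range_clip=(0, 31)),
        OutcomeSpec("adult_irritability", orientation="higher_more_severe",
                    loadings={"irritability_14": 0.65}, residual_sd=0.80,
                    mean=6, scale=6.5, range_clip=(0, 37.5)),
        OutcomeSpec("adult_css", orientation="higher_more_severe",
                    loadings={"css_9": 0.45, "irritability_14": 0.20,
                              "hyperactivity_14": 0.15},
                    residual_sd=0.95, mean=5.5, scale=2.0,
                    range_clip=(1, 10)),
        OutcomeSpec("adult_abcl", orientation="higher_more_severe",
                    loadings={"cbcl_15": 0.40}, residual_sd=1.0,
                    mean=53, scale=7, range_clip=(25, 77)),
        OutcomeSpec("adult_wbq", loadings={}, residual_sd=1.0,
                    mean=190, scale=22, range_clip=(134, 248)),
        OutcomeSpec("adult_panas_p", loadings={}, residual_sd=1.0,
                    mean=28, scale=7, range_clip=(12, 45.5)),
        OutcomeSpec("adult_panas_n", orientation="higher_more_severe",
                    loadings={}, residual_sd=1.0,
                    mean=16, scale=5.5, range_clip=(10, 35.5)),
        OutcomeSpec("adult_bdi", orientation="higher_more_severe",
                    loadings={}, residual_sd=1.0,
                    mean=6, scale=6, range_clip=(0, 30)),
        OutcomeSpec("independent_living", kind="ordinal", n_levels=3,
                    loadings={"dls_9": 0.80, "viq_9": 0.50},
                    thresholds=(-1.2, 1.4)),
        OutcomeSpec("sef_friends", kind="ordinal", n_levels=4,
                    loadings={"viq_9": 0.60, "css_9": -0.40},
                    thresholds=(-1.5, -0.3, 0.8),
                    level_values=(0, 1, 2, 3)),
        OutcomeSpec("sef_work", kind="ordinal", n_levels=7,
                    loadings={"viq_9": 0.70, "dls_9": 0.40},
                    thresholds=(-1.8, -1.0, -0.3, 0.4, 1.1, 1.9)),
    ]


def default_config(n_participants: int = 123, seed: int = 0,
                   **overrides) -> CohortConfig:
    return CohortConfig(n_participants=n_participants, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _measure_columns(measures) -> list:
    cols = []
    for m in measures:
        cols.extend(m.column(a) for a in m.ages)
    return cols


def predictor_correlation(config: CohortConfig) -> pd.DataFrame:
    """Analytic correlation matrix of the standardized measure columns.

    corr(z_{m,t}, z_{m',t'}) = loading_t * loading_{t'} * (1 if m == m'
    else trait_correlation).  Used to compute ground-truth population R².
    """
    cols, lams, names = [], [], []
    for m in config.measures:
        for a in m.ages:
            cols.append(m.column(a))
            lams.append(m.loadings[a])
            names.append(m.name)
    q = len(cols)
    C = np.eye(q)
    for i in range(q):
        for j in range(i + 1, q):
            rho = 1.0 if names[i] == names[j] else config.trait_correlation
            C[i, j] = C[j, i] = lams[i] * lams[j] * rho
    return pd.DataFrame(C, index=cols, columns=cols)


def population_r2(spec: OutcomeSpec, predictor_cov) -> float:
    """Ground-truth R² of the true linear predictor: β'Σβ / (β'Σβ + σ²).

    ``predictor_cov`` may be a DataFrame (indexed by predictor name,
    conformable with ``spec.loadings``) or a plain matrix ordered like the
    loadings.
    """
    beta = np.asarray(list(spec.loadings.values()), dtype=float)
    if beta.size == 0:
        return 0.0
    if isinstance(predictor_cov, pd.DataFrame):
        cols = list(spec.loadings.keys())
        Sigma = predictor_cov.loc[cols, cols].to_numpy()
    else:
        Sigma = np.asarray(predictor_cov, dtype=float)
    if Sigma.shape != (beta.size, beta.size):
        raise ValueError("predictor_cov not conformable with loadings")
    if np.linalg.eigvalsh((Sigma + Sigma.T) / 2).min() < -1e-8:
        raise ValueError("predictor_cov must be positive semidefinite")
    signal = float(beta @ Sigma @ beta)
    return signal / (signal + spec.residual_sd ** 2)


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a cohort table from the configured generative model.

    Deterministic given ``config.seed``.  Continuous outcomes are linear
    in the standardized generative predictors with multivariate-normal
    residuals of the configured correlation; ordinal outcomes threshold a
    unit-variance latent normal sharing that correlation.  The true
    coefficients, population R² per outcome, residual correlation and
    per-participant linear predictors are recorded in ``ground_truth``.
    """
    config.validate()
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    data = {}
    # demographics
    data["female"] = (rng.random(n) < config.p_female).astype(int)
    data["non_caucasian"] = (rng.random(n) < config.p_non_caucasian).astype(int)
    edu_p = np.asarray(config.maternal_edu_probs, dtype=float)
    edu_p = edu_p / edu_p.sum()
    data["maternal_edu"] = rng.choice(
        np.arange(1, len(edu_p) + 1), size=n, p=edu_p)

    # shared-factor traits: corr(trait_m, trait_m') = trait_correlation
    g = rng.standard_normal(n)
    a = np.sqrt(config.trait_correlation)
    b = np.sqrt(1.0 - config.trait_correlation)
    zcols = {}
    for m in config.measures:
        trait = a * g + b * rng.standard_normal(n)
        for age in m.ages:
            lam = m.loadings[age]
            z = lam * trait + np.sqrt(1.0 - lam ** 2) * rng.standard_normal(n)
            zcols[m.column(age)] = z
            data[m.column(age)] = m.means[age] + m.sd * z
        if m.name == "css":
            # current-autism-diagnosis flag, probabilistically tied to
            # concurrent symptom severity
            for age in m.ages:
                p_dx = ndtr(0.9 + 1.4 * zcols[m.column(age)])
                data[f"asd_dx_{age}"] = (rng.random(n) < p_dx).astype(int)

    n_predictors = len(data)
    if n < n_predictors:
        warnings.warn(
            f"n_participants ({n}) below number of predictors "
            f"({n_predictors}); fits will be overparameterized",
            stacklevel=2)

    # adult outcomes: eta + correlated residuals
    specs = config.outcome_specs
    K = len(specs)
    sds = np.array([s.residual_sd for s in specs])
    cov = config.residual_correlation * np.outer(sds, sds)
    # eigen-based factor tolerates semidefinite matrices
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    resid = rng.standard_normal((n, K)) @ L.T

    etas = {}
    truth_outcomes = {}
    pred_corr = predictor_correlation(config)
    for k, spec in enumerate(specs):
        eta = np.zeros(n)
        for col, beta in spec.loadings.items():
            if col not in zcols:
                raise KeyError(f"outcome {spec.name} loads on unknown "
                               f"generative column {col!r}")
            eta += beta * zcols[col]
        etas[spec.name] = eta
        latent = eta + resid[:, k]
        if spec.kind == "continuous":
            y = spec.mean + spec.scale * latent
            if config.clip_outcomes and spec.range_clip is not None:
                y = np.clip(y, *spec.range_clip)
            data[spec.name] = y
        else:
            idx = np.searchsorted(np.asarray(spec.thresholds), latent,
                                  side="left")
            data[spec.name] = np.asarray(spec.level_values)[idx]
        truth_outcomes[spec.name] = {
            "loadings": dict(spec.loadings),
            "residual_sd": spec.residual_sd,
            "population_r2": population_r2(spec, pred_corr),
            "kind": spec.kind,
            "thresholds": list(spec.thresholds),
        }

    frame = pd.DataFrame(data)
    truth = {
        "outcomes": truth_outcomes,
        "residual_correlation": config.residual_correlation.copy(),
        "linear_predictors": pd.DataFrame(etas),
        "seed": config.seed,
    }
    return CohortTable(data=frame, ground_truth=truth, config=config)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

#: columns blanked together when a participant drops out at a given wave
_WAVES = {
    3: ["viq_3", "nviq_3", "css_3", "dls_3", "asd_dx_3"],
    5: ["viq_5", "nviq_5", "css_5", "dls_5", "asd_dx_5"],
    9: ["viq_9", "nviq_9", "css_9", "dls_9", "asd_dx_9",
        "irritability_9", "hyperactivity_9", "cbcl_9"],
    14: ["irritability_14", "hyperactivity_14", "sdq_emotion_14",
         "sdq_prosocial_14"],
    15: ["cbcl_15"],
    17: ["irritability_17", "hyperactivity_17", "sdq_emotion_17",
         "sdq_prosocial_17"],
}


def apply_missingness(table: CohortTable, spec: MissingnessSpec,
                      seed: int) -> CohortTable:
    """Blank entries per the missingness specification.

    Item-level blanking is MCAR per column; whole-wave dropout is MAR via a
    logistic model on race and maternal education (monotone: once dropped,
    all later waves and the adult outcomes are missing).  The complete data
    are kept in ``ground_truth['complete_data']`` so imputation can be
    scored against truth.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    n = len(df)
    outcome_cols = (list(table.config.outcome_names)
                    if table.config is not None else [])

    # MAR whole-wave dropout
    co = spec.mar_coefficients
    lin = (co.get("intercept", -10.0)
           + co.get("non_caucasian", 0.0) * df["non_caucasian"].to_numpy()
           + co.get("maternal_edu", 0.0)
           * (df["maternal_edu"].to_numpy() - 3.0))
    dropped = rng.random(n) < expit(lin)
    wave_ages = sorted(_WAVES)
    start_wave = rng.integers(0, len(wave_ages), size=n)
    for i in np.flatnonzero(dropped):
        for age in wave_ages[start_wave[i]:]:
            for col in _WAVES[age]:
                if col in df.columns:
                    df.loc[df.index[i], col] = np.nan
        for col in outcome_cols:
            df.loc[df.index[i], col] = np.nan

    # item-level MCAR blanking (never demographics)
    for col in df.columns:
        if col in DEMOGRAPHICS:
            continue
        p = spec.item_prob(col)
        if p > 0:
            mask = rng.random(n) < p
            df.loc[mask, col] = np.nan

    for col in outcome_cols:
        p = spec.outcome_prob(col)
        if p > 0:
            mask = rng.random(n) < p
            df.loc[mask, col] = np.nan

    truth = dict(table.ground_truth)
    truth["complete_data"] = table.data.copy()
    truth["dropout_flag"] = dropped.copy()
    return CohortTable(data=df, ground_truth=truth, config=table.config)


# ---------------------------------------------------------------------------
# priorities
# ---------------------------------------------------------------------------

def generate_priority_profile(seed: int, concentration: float = 1.0):
    """Draw a priority questionnaire: 100 points over the 10 facets.

    Points follow a Dirichlet-multinomial with symmetric concentration
    ``concentration`` per facet: large values approach an equal 10-points-
    per-facet profile, small values concentrate points on few facets.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    from .composite import PriorityProfile  # avoid import cycle at load

    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(10, concentration))
    points = rng.multinomial(100, p)
    return PriorityProfile(facet_points=points.astype(float),
                           labels=list(FACET_LABELS))


def default_orientation_map(outcome_specs=None,
                            convention: str = "higher_less_severe") -> dict:
    """Per-outcome orientation signs for standardization.

    With the default convention, signs flip severity-scored outcomes so
    that higher oriented scores always mean a less severe impact; the
    opposite convention (positive = more severe impact) is available as a
    switch since both appear in practice.
    """
    if convention not in ("higher_less_severe", "higher_more_severe"):
        raise ValueError(f"unknown convention {convention!r}")
    specs = default_outcomes() if outcome_specs is None else outcome_specs
    flip = 1.0 if convention == "higher_less_severe" else -1.0
    return {s.name: flip * s.sign for s in specs}
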