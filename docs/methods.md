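# Methods

`outcomecast` implements an analysis pipeline for asking, of a cohort of
children referred to autism services and followed into adulthood, *which
facets of the adult outcome are predictable, from what age, and how
uncertain any individual prediction is*. Because cohorts of this kind are
sensitive and non-shareable, the package pairs the analysis machinery with
a synthetic-cohort generator whose generative model is exactly the model
the analysis assumes, so every stage can be validated by parameter
recovery.

## The prediction models

A separate model is fit for each adult outcome at each of nine model
timepoints (ages 2, 3, 5, 9, 14, 14\*, 15, 17, 17\*; the starred labels
add two teacher-reported SDQ subscales). Every model includes gender,
race, and maternal education; the childhood core measures (verbal and
non-verbal IQ, ADOS calibrated severity, Vineland daily-living standard
score, current autism diagnosis) enter at their own age up to 9 and are
frozen at age-9 values afterwards; each adolescent behavioural measure
(ABC irritability and hyperactivity, CBCL total, SDQ subscales) is
represented only by its most recent assessment.

**Continuous outcomes** use the lasso,

  minimize (1/2n)·‖y − β₀ − Xβ‖² + λ·Σⱼ|βⱼ|,

with the intercept unpenalized and predictors standardized internally.
λ is chosen to minimize the leave-one-out (LOO) mean squared error over a
100-point log-spaced grid from λ_max (the smallest penalty zeroing all
slopes, max_j |x_jᵀ(y − ȳ)|/n on standardized columns) down to
0.001·λ_max, ties resolved toward the sparser model. An unpenalized OLS
variant is available for comparison.

**Ordinal outcomes** (independent living, friendship, work, on 3/4/7-level
scales) use proportional-odds regression, P(Y ≤ j | x) =
logistic(θⱼ − xᵀβ) with strictly increasing thresholds, fit by maximum
likelihood (statsmodels' `OrderedModel`, whose unconstrained log-gap
threshold parameterization guarantees monotonicity). No penalty is used:
sparse outcome categories make cross-validated tuning unstable, so these
models stay unpenalized by design. Intercept-only models are solved in
closed form (thresholds = empirical cumulative logits).

## Optimism correction

Apparent (resubstitution) performance overstates out-of-sample
performance, especially at n ≈ 100–150 with 8–13 predictors.

* Continuous: **nested leave-one-out cross-validation**. For every
  held-out row the *entire* procedure — including re-selection of λ by an
  inner LOOCV on the remaining n−1 rows — is refit, so no information
  leaks from the held-out observation. Corrected R² = 1 − Σ(yᵢ −
  ŷ₋ᵢ)²/Σ(yᵢ − ȳ)², with ȳ the full-sample mean (switchable); negative
  values are legitimate and mean the model predicts worse than the mean.
  A non-nested mode (λ fixed at the full-data choice) is provided for
  comparison and is slightly optimistic.
* Ordinal: **Harrell's bootstrap** (40 repetitions by default). Each
  resample refits the model; optimism_b = c(model_b on resample) −
  c(model_b on original data); corrected c = apparent c − mean optimism.
  Resamples missing an outcome level are redrawn (cap 100) rather than
  collapsing levels, keeping the model dimension constant across
  repetitions.

Discrimination is the **generalized c-statistic**: over all pairs with
different outcome levels, the probability that the linear predictor xᵀβ
orders the pair concordantly, ties counting ½. It is computed from
level-pairwise rank sums (equivalent to Mann–Whitney U) and verified in
the tests against O(n²) pair enumeration.

## Nested-LOOCV implementation

The double LOO loop needs ~n² penalty-path fits per outcome. Coordinate
descent therefore runs on the standardized Gram matrix (one sweep is
O(p²), independent of n), fold statistics are maintained by rank-one
downdates of X'X, X'y and the column sums, and the hot loops are
numba-compiled with glmnet-style active-set sweeps. Convergence is
declared when the largest coefficient change in a sweep falls below 1e−7;
penalty-*selection* sweeps use 1e−4 (the LOO-MSE curve is flat at that
scale, and only the argmin matters), while every reported fit uses the
strict tolerance. λ = 0 falls back to exact least squares. The
implementation is cross-checked in the tests against scikit-learn's
`Lasso` (same objective) and against soft-threshold closed forms on
orthonormal designs.

## Preprocessing

* **Pro-rating:** a partially completed scale is scored as
  mean(answered) × n_items when ≥ 80% of items were answered, else
  missing.
* **KNN imputation** (k = 5): distances are Euclidean over the
  coordinates both rows have observed, on column-standardized values,
  rescaled by (total coordinates / shared observed coordinates) —
  scikit-learn's `nan_euclidean_distances`. Continuous cells take the
  neighbour mean; binary/ordinal cells the neighbour mode with ties to
  the lowest level; distance ties break by row order, so imputation is
  deterministic. Imputation runs on the whole table before any
  validation split (the split-then-impute alternative changes little here
  but is not what this pipeline does). Rows missing an *outcome* are
  excluded from that outcome's single-outcome analysis; for the joint
  model, outcomes are imputed like predictors.
* **Standardization:** each outcome is centred and scaled to unit sample
  variance (divisor n − 1; the convention is recorded in the transform
  object) and oriented by a per-outcome sign. The default convention
  makes *higher standardized scores mean a less severe impact*; the
  opposite convention is a config switch, since both appear in applied
  reports.

## Joint model and composite prediction intervals

Priorities are elicited as up to 100 points over 10 facets of the adult
outcome; a row-stochastic 10 × K facet-to-outcome map turns points into
outcome weights w = (points/100)ᵀM. The default map assigns each facet
uniformly to a curated outcome subset and is fully configurable — any
actual elicitation instrument's mapping can be supplied as JSON/CSV.

All K outcomes are modeled jointly on one predictor set: continuous
outcomes by OLS on the standardized scale, ordinal outcomes by probit
regression on a unit-variance latent scale. Each ordinal latent scale is
re-centred at its cohort mean (the fitted thresholds are shifted by the
same amount, leaving all category probabilities unchanged), so every
composite component — standardized continuous or latent ordinal — is
mean-zero over the training cohort and the components are directly
summable. With identical regressors
across equations, these outcome-wise fits coincide with the joint
weighted-least-squares (seemingly-unrelated-regression/SEM) solution, so
the two-stage route is used: per-outcome fits, then pairwise residual
correlations — Pearson (continuous–continuous), polyserial
(continuous–ordinal) and polychoric (ordinal–ordinal), the latter two by
1-D maximum likelihood over interval-censored latent residuals — and a
projection to the nearest positive-semidefinite correlation matrix
(eigenvalue clipping + unit-diagonal rescaling; the Frobenius adjustment
distance is recorded and is zero when no projection was needed).
Rectangle probabilities for the polychoric likelihood use a vectorized
Drezner–Wesolowsky/Genz bivariate-normal CDF, accurate to ~5e−9 and
validated against scipy's reference implementation.

For a new predictor vector x (augmented with 1) and training Gram inverse
G = (XᵀX)⁻¹:

* single outcome k: point = xᵀb_k, se² = σ_kk·(1 + xᵀGx), where σ_kk is
  the estimated residual variance (RSS/(n−p−1)) on the standardized scale
  and exactly 1 on the ordinal latent scale;
* composite with weights w: point = wᵀ(Bx), se² = (1 + xᵀGx)·(wᵀSw) with
  S = D^{1/2}·R·D^{1/2} the residual covariance. A one-hot w therefore
  reduces *exactly* to the single-outcome interval, and with independent
  unit-variance residuals and equal weights se² = (1 + xᵀGx)/K — the
  formal version of "weakly correlated prediction errors pull composite
  predictions toward the average".

Intervals are point ± z·se at the 95% level by default; ordinal
predictions are reported on the latent scale with the fitted thresholds
attached for interpretation. Composite points use the unpenalized joint
fit (matching the SEM route); substituting lasso point predictions under
the same interval machinery is a config option.

## Sample-size planning

`riley_min_r2` implements the shrinkage-factor criterion: the smallest
anticipated R² for which a linear model with p predictors on n
observations keeps its expected uniform shrinkage above S (default 0.9),
solved in closed form as R² = S·(1 − exp(p/(n·(S − 1)))) and verified
against a bisection oracle. At (n = 123, p = 10, S = 0.9) this variant
gives ≈ 0.50. Published applications of such criteria sometimes print
other values depending on which of the related criteria (or their
maximum) is applied; the variant identifier is recorded with every result
and no attempt is made to reproduce any particular printed value.

Performance figures draw dashed test–retest ceiling lines: an outcome
with test–retest ICC ρ cannot be predicted above R² = ρ² once both the
outcome and its own earlier measurement carry the same unreliability.
The mapping is isolated in `icc_ceiling` and is a rendering choice, not a
fitted quantity.

## The synthetic-cohort generator

Defaults emulate a referred-for-autism early-diagnosis cohort: n = 123;
17% female, 17% non-Caucasian, maternal education on a 1–5 ordinal scale;
core measures at ages 2–9 and behavioural measures at 9–17 built as
mean + sd·(λ_t·trait + √(1−λ_t²)·noise) with loadings λ rising with age
(0.6 → 0.9), traits sharing a general factor (cross-measure trait
correlation 0.5); marginal means/SDs loosely calibrated to published
descriptive ranges (e.g. adult verbal IQ spanning 2–139, independent
living on 1–3). Fourteen adult outcomes (11 continuous, 3 ordinal with
3/4/7 levels) are linear in the standardized generative predictors with
jointly multivariate-normal residuals; ordinal outcomes threshold a
unit-variance latent sharing that residual correlation. Loadings are set
to reproduce the qualitative predictability gradient reported for such
cohorts — cognitive/adaptive outcomes strongly predicted by their age-9
analogues, behavioural outcomes moderately predicted by adolescent
measures, well-being/affect/depression outcomes essentially
unpredictable. Cross-outcome residual correlation defaults to 0.2
(published analyses describe these correlations only as "weak", so the
magnitude is a simulation choice, not an empirical value).

Missingness: item-level MCAR blanking per column, plus monotone
whole-wave dropout from logistic(intercept + b·non_caucasian +
b·(maternal_edu − 3)) — missing at random given demographics, emulating
the association of attrition with race and parental education. Dropout
also blanks the adult outcomes. Demographics are never blanked.

Ground truth (true coefficients, analytic population R² per outcome —
βᵀΣβ/(βᵀΣβ + σ²) with Σ the analytic predictor correlation — residual
correlation, per-participant linear predictors, pre-missingness values)
travels with the table for recovery tests.

What the generator does *not* emulate: floor/ceiling effects and skewness
of real psychometric scales (clipping to plausible ranges exists but is
off by default because it distorts R²-recovery tests), informative
(MNAR) dropout, measurement error correlated across instruments, cohort
effects, and any real joint distribution. Passing recovery tests
therefore shows the *procedures* are correct and calibrated under their
own assumptions — not that real cohorts satisfy those assumptions.

## Numerical and design choices

* Penalty selection deliberately uses plain min-MSE LOOCV (no 1-SE rule),
  matching the stated procedure; on null data this selects the empty
  model only ~60% of the time because LOO-MSE differences are then
  noise-dominated. Tests assert the majority behaviour, not certainty.
* The corrected-R² denominator uses the full-sample mean; fold-specific
  means are available behind a switch.
* Lasso falls back to exact least squares at λ = 0; constant columns get
  coefficient zero; rank-deficient OLS returns the flagged minimum-norm
  solution.
* Polyserial/polychoric MLEs are bounded to |ρ| ≤ 0.999; likelihood terms
  are floored at 1e−300; BVN arguments are clamped to ±8 (tail mass
  < 1e−15), which also makes open-ended ordinal categories well-defined.
* The c-statistic is undefined when all outcomes share one level
  (explicit error); bootstrap repetitions that cannot produce a usable
  refit after 100 redraws are skipped and logged, and fewer than 10
  usable repetitions is an error.
* Determinism: every stochastic step takes an explicit seed;
  grid-cell bootstrap seeds are derived from (run seed, outcome, label).

## Problem sizes in tests and the acceptance script

Recovery studies run at the sizes the properties need, chosen once:
corrected-R² calibration at n = 120, p = 10 over 20 seeds (tests) / 10
seeds per signal level (acceptance script); null c-statistic calibration
at n = 150 over 50 / 20 seeds with the default 40-repetition bootstrap;
latent-correlation recovery at n = 5000; composite-interval coverage over
20 × 2000 (tests) / 10 × 1000 (script) train/test draws; the
demonstration performance grid uses two contrasting outcomes at ages 2
and 9 on the default n = 123 cohort. The full 14-outcome × 9-timepoint
grid is run via the CLI (`outcomecast validate`), at roughly two minutes
on a laptop-class core.

## Known limitations

* The facet-to-outcome map is a package default, not an elicited
  instrument; substantive use requires supplying the real mapping.
* Ordinal components of composites live on the latent probit scale;
  mixing latent-scale and standardized-scale components is coherent
  (both are unit-variance severity-oriented scales) but the latent scale
  is not directly observable.
* Prediction intervals carry parameter uncertainty only through the
  shared (1 + xᵀGx) factor, exact for identical designs across outcomes;
  threshold-estimation uncertainty for ordinal outcomes is ignored.
* No elastic net, no partial proportional odds, no multiple imputation,
  no confidence intervals on performance metrics — all deliberately out
  of scope.
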