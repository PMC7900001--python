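"""Priority weights, joint residual model, composite prediction intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from outcomecast import (
    CohortConfig,
    FacetOutcomeMap,
    JointOutcomeModel,
    OutcomeSpec,
    PriorityProfile,
    StandardizeTransform,
    bvn_cdf,
    default_facet_map,
    fit_joint_model,
    generate_cohort,
    map_priorities_to_weights,
    nearest_psd_correlation,
    predict_composite_interval,
    predict_outcome_interval,
    FACET_LABELS,
)


class TestPriorityWeights:
    def test_uniform_profile_block_identity_map_gives_equal_weights(self):
        prof = PriorityProfile(np.full(10, 10.0))
        fmap = FacetOutcomeMap(np.eye(10), list(FACET_LABELS),
                               [f"o{i}" for i in range(10)])
        w = map_priorities_to_weights(prof, fmap)
        np.testing.assert_allclose(w.to_numpy(), 0.1)

    def test_all_points_on_one_facet_gives_one_hot(self):
        pts = np.zeros(10)
        pts[3] = 100.0
        prof = PriorityProfile(pts)
        fmap = FacetOutcomeMap(np.eye(10), list(FACET_LABELS),
                               [f"o{i}" for i in range(10)])
        w = map_priorities_to_weights(prof, fmap)
        assert w["o3"] == 1.0 and w.drop("o3").eq(0).all()

    def test_sixty_forty_split_over_pairs(self):
        pts = np.zeros(10)
        pts[0], pts[1] = 60.0, 40.0
        M = np.zeros((10, 4))
        M[0, 0] = M[0, 1] = 0.5
        M[1, 2] = M[1, 3] = 0.5
        M[2:, 0] = 1.0  # unused facets must still be row-stochastic
        prof = PriorityProfile(pts)
        fmap = FacetOutcomeMap(M, list(FACET_LABELS), list("abcd"))
        w = map_priorities_to_weights(prof, fmap)
        np.testing.assert_allclose(w.to_numpy(), [0.3, 0.3, 0.2, 0.2])

    def test_overspent_points_rejected(self):
        with pytest.raises(ValueError, match="at most 100"):
            PriorityProfile(np.full(10, 11.0))

    def test_negative_points_rejected(self):
        pts = np.full(10, 10.0)
        pts[0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            PriorityProfile(pts)

    def test_non_stochastic_map_rejected(self):
        M = np.full((10, 2), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            FacetOutcomeMap(M, list(FACET_LABELS), ["a", "b"])

    def test_default_map_covers_all_default_outcomes(self):
        from outcomecast import default_outcomes

        names = [s.name for s in default_outcomes()]
        fmap = default_facet_map(names)
        assert fmap.matrix.sum(axis=0).min() > 0  # every outcome reachable


class TestBvnCdf:
    def test_matches_scipy_oracle(self, rng):
        for rho in (-0.95, -0.6, 0.0, 0.4, 0.93, 0.99):
            x = rng.uniform(-3, 3, 20)
            y = rng.uniform(-3, 3, 20)
            ref = [multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf(p)
                   for p in zip(x, y)]
            np.testing.assert_allclose(bvn_cdf(x, y, rho), ref, atol=5e-9)

    def test_infinite_bounds_reduce_to_marginals(self):
        from scipy.special import ndtr

        assert bvn_cdf(np.inf, 0.7, 0.5) == pytest.approx(ndtr(0.7))
        assert bvn_cdf(-np.inf, 0.7, 0.5) == pytest.approx(0.0)


class TestNearestPsd:
    def test_psd_input_untouched(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        out, dist = nearest_psd_correlation(R)
        assert dist == 0.0
        np.testing.assert_allclose(out, R)

    def test_non_psd_projected_with_positive_distance(self):
        R = np.array([[1.0, 0.95, -0.95],
                      [0.95, 1.0, 0.95],
                      [-0.95, 0.95, 1.0]])
        out, dist = nearest_psd_correlation(R)
        assert dist > 0
        assert np.linalg.eigvalsh(out).min() >= 0
        np.testing.assert_allclose(np.diag(out), 1.0)


def _joint_cohort(R, specs, n, seed=0):
    cfg = CohortConfig(n_participants=n, seed=seed, outcome_specs=specs,
                       residual_correlation=np.asarray(R, dtype=float))
    return generate_cohort(cfg), cfg


PREDICTORS = ["viq_9", "dls_9", "css_9"]


def _fit(table, cfg):
    cont = [s.name for s in cfg.outcome_specs if s.kind == "continuous"]
    ordn = [s.name for s in cfg.outcome_specs if s.kind == "ordinal"]
    orient = {s.name: 1.0 for s in cfg.outcome_specs}
    return fit_joint_model(table, PREDICTORS, cont, ordn, orient)


class TestJointModel:
    def test_pearson_residual_correlation_recovery(self):
        specs = [OutcomeSpec("y1", loadings={"viq_9": 0.8}, residual_sd=0.8),
                 OutcomeSpec("y2", loadings={"dls_9": 0.6}, residual_sd=1.0)]
        table, cfg = _joint_cohort([[1, 0.5], [0.5, 1]], specs, 4000)
        model = _fit(table, cfg)
        assert model.R[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_independent_outcomes_near_zero_offdiagonal(self):
        specs = [OutcomeSpec("y1", loadings={"viq_9": 0.8}, residual_sd=0.8),
                 OutcomeSpec("y2", loadings={"dls_9": 0.6}, residual_sd=1.0),
                 OutcomeSpec("liv", kind="ordinal", n_levels=3,
                             loadings={"dls_9": 0.7}, thresholds=(-1, 1))]
        table, cfg = _joint_cohort(np.eye(3), specs, 4000)
        model = _fit(table, cfg)
        off = model.R[np.triu_indices(3, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_polyserial_latent_correlation_recovery(self):
        specs = [OutcomeSpec("y1", loadings={"viq_9": 0.8}, residual_sd=0.9),
                 OutcomeSpec("liv", kind="ordinal", n_levels=3,
                             loadings={"dls_9": 0.7}, thresholds=(-1, 1))]
        table, cfg = _joint_cohort([[1, 0.6], [0.6, 1]], specs, 4000)
        model = _fit(table, cfg)
        assert model.R[0, 1] == pytest.approx(0.6, abs=0.07)

    def test_missing_outcome_rejected(self):
        specs = [OutcomeSpec("y1", loadings={"viq_9": 0.8})]
        table, cfg = _joint_cohort(np.eye(1), specs, 200)
        table.data.loc[0, "y1"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            _fit(table, cfg)


def _toy_model(K=4, n=100, resid_sd=1.0, seed=0):
    """Hand-assembled intercept-plus-one-predictor model with R = I."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 1))
    Xa = np.column_stack([np.ones(n), X])
    G = np.linalg.inv(Xa.T @ Xa)
    names = [f"o{k}" for k in range(K)]
    return JointOutcomeModel(
        outcome_names=names,
        kinds={o: "continuous" for o in names},
        coefficients={o: (0.1 * k, np.array([0.5 + 0.1 * k]))
                      for k, o in enumerate(names)},
        thresholds={}, resid_sd={o: resid_sd for o in names},
        R=np.eye(K), R_raw=np.eye(K), psd_adjustment=0.0, G=G,
        predictor_columns=["x"], transform=StandardizeTransform(), n_used=n)


class TestPredictionIntervals:
    def test_one_hot_weights_reduce_to_single_outcome(self):
        model = _toy_model(resid_sd=0.7)
        x = np.array([0.8])
        single = predict_outcome_interval(model, x, "o2")
        w = np.array([0.0, 0.0, 1.0, 0.0])
        comp = predict_composite_interval(model, x, w)
        assert comp.point == pytest.approx(single.point)
        assert comp.se_pred == pytest.approx(single.se_pred)
        assert comp.interval == pytest.approx(single.interval)

    def test_identity_residuals_equal_weights_closed_form(self):
        K = 4
        model = _toy_model(K=K, resid_sd=1.0)
        x = np.array([1.3])
        xa = np.array([1.0, 1.3])
        lev = xa @ model.G @ xa
        comp = predict_composite_interval(model, x, np.full(K, 1.0 / K))
        assert comp.se_pred ** 2 == pytest.approx((1 + lev) / K)

    def test_interval_narrows_as_outcomes_added(self):
        x = np.array([0.5])
        widths = []
        for K in (2, 4, 8):
            model = _toy_model(K=K)
            comp = predict_composite_interval(model, x, np.full(K, 1.0 / K))
            widths.append(comp.interval[1] - comp.interval[0])
        assert widths[0] > widths[1] > widths[2]

    def test_composite_point_is_weighted_sum_of_single_points(self):
        model = _toy_model()
        x = np.array([-0.4])
        w = np.array([0.1, 0.2, 0.3, 0.4])
        singles = [predict_outcome_interval(model, x, o).point
                   for o in model.outcome_names]
        comp = predict_composite_interval(model, x, w)
        assert comp.point == pytest.approx(float(w @ singles), abs=1e-12)

    def test_width_monotone_in_residual_variance_and_leverage(self):
        x = np.array([0.5])
        w = np.full(4, 0.25)
        base = predict_composite_interval(_toy_model(resid_sd=1.0), x, w)
        inflated = predict_composite_interval(_toy_model(resid_sd=1.5), x, w)
        assert inflated.se_pred > base.se_pred
        model = _toy_model()
        far = predict_composite_interval(model, np.array([4.0]), w)
        near = predict_composite_interval(model, np.array([0.0]), w)
        assert far.se_pred > near.se_pred

    def test_intercept_only_textbook_se(self):
        # se² = s²(1 + 1/n) when the design is an intercept alone
        rng = np.random.default_rng(5)
        n = 80
        df = pd.DataFrame({"y": rng.normal(0, 2, n)})
        from outcomecast import CohortTable

        table = CohortTable(data=df)
        model = fit_joint_model(table, [], ["y"], [], {"y": 1.0})
        pred = predict_outcome_interval(model, np.empty(0), "y")
        # on the standardized scale s² is RSS/(n-1) of the z-scores = 1
        assert pred.se_pred ** 2 == pytest.approx(1.0 + 1.0 / n, rel=0.05)

    def test_interval_width_matches_level(self):
        model = _toy_model()
        x = np.array([0.2])
        p95 = predict_outcome_interval(model, x, "o0", level=0.95)
        from scipy.special import ndtri

        width = p95.interval[1] - p95.interval[0]
        assert width == pytest.approx(2 * ndtri(0.975) * p95.se_pred)

    def test_zero_and_negative_weights_rejected(self):
        model = _toy_model()
        with pytest.raises(ValueError, match="all-zero"):
            predict_composite_interval(model, np.array([0.0]), np.zeros(4))
        with pytest.raises(ValueError, match="non-negative"):
            predict_composite_interval(model, np.array([0.0]),
                                       np.array([0.5, -0.5, 0.5, 0.5]))

    def test_unknown_outcome_rejected(self):
        with pytest.raises(KeyError):
            predict_outcome_interval(_toy_model(), np.array([0.0]), "nope")


def test_reference_child_profile_accepted():
    """A concrete clinical-style predictor profile (age-9 VIQ 101, NVIQ 95,
    DLS 45, CSS 4; age-14 irritability 1, hyperactivity 4; age-15 CBCL 50)
    is valid input and yields finite intervals for every outcome."""
    import outcomecast as oc

    cfg = oc.default_config(seed=2)
    table = oc.generate_cohort(cfg)
    specs = oc.default_predictor_sets()["15"]
    cont = [s.name for s in cfg.outcome_specs if s.kind == "continuous"]
    ordn = [s.name for s in cfg.outcome_specs if s.kind == "ordinal"]
    orient = oc.default_orientation_map(cfg.outcome_specs)
    model = oc.fit_joint_model(table, specs.columns, cont, ordn, orient)
    child = {"female": 0, "non_caucasian": 0, "maternal_edu": 3,
             "viq_9": 101, "nviq_9": 95, "css_9": 4, "dls_9": 45,
             "asd_dx_9": 1, "irritability_14": 1, "hyperactivity_14": 4,
             "cbcl_15": 50}
    x = np.array([float(child[c]) for c in specs.columns])
    for o in model.outcome_names:
        pr = predict_outcome_interval(model, x, o)
        assert np.isfinite([pr.point, pr.se_pred, *pr.interval]).all()
        assert pr.interval[0] < pr.point < pr.interval[1]
        if o in model.thresholds:
            assert pr.thresholds is not None
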