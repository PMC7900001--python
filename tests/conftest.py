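import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """Complete default cohort (no missingness), n = 123, seed 0."""
    from outcomecast import default_config, generate_cohort

    return generate_cohort(default_config(seed=0))


@pytest.fixture(scope="session")
def missing_cohort():
    """Default cohort with item blanking and MAR dropout applied."""
    from outcomecast import (MissingnessSpec, apply_missingness,
                             default_config, generate_cohort)

    cfg = default_config(seed=0)
    spec = MissingnessSpec(
        item_missing_prob=0.05,
        mar_coefficients={"intercept": -2.0, "non_caucasian": 0.8,
                          "maternal_edu": -0.3},
        outcome_missing_prob=0.08,
    )
    table = generate_cohort(cfg)
    return apply_missingness(table, spec, seed=1)


@pytest.fixture(scope="session")
def imputed_cohort(missing_cohort):
    from outcomecast import knn_impute

    return knn_impute(missing_cohort, k=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
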