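import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import probio_sim as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return ps.default_catalog()


@pytest.fixture(scope="session")
def joint(catalog):
    return ps.calibrate_joint_prevalence(catalog)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def short_null_scenario():
    """A cheap null platform: 2 drugs, 18 months."""
    return ps.null_scenario(n_drugs=2, horizon_months=18)


@pytest.fixture()
def quick_graduation_scenario():
    """Thresholds relaxed so a strongly effective drug graduates within a
    short horizon; used for structural (not statistical) assertions."""
    thresholds = ps.DecisionThresholds(
        graduation_prob=0.60,
        futility_prob=0.05,
        min_n_signature=5,
        consistency_min_n=50,  # vacuous: structural tests only
    )
    return ps.single_effect_scenario(
        15.0,
        signature="All",
        n_drugs=1,
        horizon_months=36,
        thresholds=thresholds,
    )
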