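import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import envemass as em

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

INSULIN = "C254H377N65O75S6"
MYOGLOBIN = "C769H1212N210O218S2"


@pytest.fixture(scope="session")
def insulin():
    return em.parse_formula(INSULIN)


@pytest.fixture(scope="session")
def myoglobin():
    return em.parse_formula(MYOGLOBIN)


@pytest.fixture(scope="session")
def averagine():
    return em.AveragineModel.default()


@pytest.fixture(scope="session")
def published():
    return em.PROFILES["published"]


@pytest.fixture(scope="session")
def small_proteome():
    """300 synthetic proteins reused across property tests."""
    return em.sample_proteome(300, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
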