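import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-parameter cohort shared by read-only tests."""
    from chplanimetry import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=1234, n_subjects=600))


@pytest.fixture
def rng():
    return np.random.default_rng(99)
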