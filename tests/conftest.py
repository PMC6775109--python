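import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_pair():
    """One independent 10 Hz Poisson pair over an hour (null fixture)."""
    from glmcc import generate_independent_poisson
    return generate_independent_poisson([10.0, 10.0], 3600.0, seed=42)


@pytest.fixture(scope="session")
def coupled_pair():
    """A strongly coupled generator pair (J12=1, tau=4 ms, d=1 ms)."""
    from glmcc import GlmPairConfig, generate_glm_pair
    return generate_glm_pair(GlmPairConfig(j12=1.0, T=3600.0, seed=7))
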