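import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ramplab import KineticsParams, RampProtocol, simulate_session

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return RampProtocol()


@pytest.fixture(scope="session")
def noiseless():
    """Noise-free default session with its analytic ground truth."""
    session, truth = simulate_session(KineticsParams(noise_sd=0.0), seed=0)
    return session, truth


@pytest.fixture()
def make_session():
    """Factory for sessions with parameter overrides."""
    def _make(seed=0, **overrides):
        return simulate_session(KineticsParams(**overrides), seed=seed)
    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
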