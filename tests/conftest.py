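import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tendonmech.core import LoadingProtocol

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol():
    """Full study protocol (500 cycles)."""
    return LoadingProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Reduced protocol for fast unit tests: 5 s preload, 10 cycles."""
    return LoadingProtocol(preload_duration=5.0, cycle_count=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
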