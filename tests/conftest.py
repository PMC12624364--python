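import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry():
    """16^3 phantom with 20 GM regions (shared across tests)."""
    from restcvr.synth import default_geometry

    return default_geometry((16, 16, 16), 20)


@pytest.fixture(scope="session")
def geometry_91():
    """Default 20^3 phantom with the study's 91-region parcellation."""
    from restcvr.synth import default_geometry

    return default_geometry((20, 20, 20), 91)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
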