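import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def methods_profile():
    from decobubble import make_fixture_profile

    return make_fixture_profile("methods_exposure")


@pytest.fixture(scope="session")
def methods_venous(methods_profile):
    """Tension series for the chamber exposure (saline bath: no alveolar
    water-vapor step)."""
    from decobubble import run_profile

    return run_profile(methods_profile, water_vapor_kpa=0.0)
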