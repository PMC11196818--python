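import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ductiometry import BiometricModel
from ductiometry.simulate import reference_from_biometrics

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def biometrics():
    return BiometricModel()


@pytest.fixture(scope="session")
def circle_reference(biometrics):
    """Ideal circular reference limbus (radius 5.875 mm at z = 10.45 mm)."""
    return reference_from_biometrics(biometrics, n_ring=180)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
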