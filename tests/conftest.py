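import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fiborient as fo

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grating45():
    """Noise-free sinusoidal grating with fiber axis at 45 degrees."""
    spec = fo.PhantomSpec(
        families=({"orientation": 45.0, "period": 10.0},), seed=0
    )
    return fo.make_fiber_image(spec)


@pytest.fixture(scope="session")
def grating45_field(grating45):
    return fo.compute_gradient(grating45, R=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
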