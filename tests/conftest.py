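import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_montage():
    from eegcomplex import gen_montage

    return gen_montage(6)


@pytest.fixture(scope="session")
def sine_recording():
    """Two-channel 10-s recording: 10 Hz sine and white noise, 500 Hz."""
    from eegcomplex import Montage, Recording

    t = np.arange(5000) / 500.0
    rng = np.random.default_rng(7)
    data = np.vstack([5 * np.sin(2 * np.pi * 10 * t), rng.standard_normal(5000)])
    montage = Montage(("sine", "noise"), np.array([[0.0, 0.0], [1.0, 0.0]]))
    return Recording(data, 500.0, montage)
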