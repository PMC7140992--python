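import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_shape(rng, k=21):
    """Random centered, unit-size configuration."""
    x = rng.normal(size=(k, 2))
    x -= x.mean(axis=0)
    return x / np.sqrt((x**2).sum())


def rotation(theta_deg):
    t = np.deg2rad(theta_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
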