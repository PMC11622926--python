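import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from krfbho.preprocessing import CONTINUOUS, DISCRETE, FeatureTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_table():
    """60 rows where feature 0 alone determines the label exactly."""
    gen = np.random.default_rng(0)
    n = 60
    y = np.tile([0, 1], n // 2)
    x0 = y * 2.0 - 1.0 + gen.normal(0, 0.05, n)
    noise = gen.normal(0, 1, (n, 3))
    values = np.column_stack([x0, noise])
    return FeatureTable(
        ["signal", "n1", "n2", "n3"], [CONTINUOUS] * 4, values, y
    )


def make_planted_table(n=300, seed=0, n_noise=9):
    """Binary-label table where features 0..3 carry the signal."""
    gen = np.random.default_rng(seed)
    signal = gen.normal(0, 1, (n, 4))
    logit = signal @ np.array([2.0, 1.8, -1.9, 1.7])
    p = 1 / (1 + np.exp(-logit))
    y = (gen.random(n) < p).astype(int)
    noise = gen.normal(0, 1, (n, n_noise))
    values = np.column_stack([signal, noise])
    names = [f"f{i}" for i in range(4 + n_noise)]
    return FeatureTable(names, [CONTINUOUS] * len(names), values, y)


@pytest.fixture
def planted_table():
    return make_planted_table()
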