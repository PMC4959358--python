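import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, database=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_parties():
    """Two parties, 60 pooled records, 3 binary features + intercept."""
    from smacglore import SimSpec, simulate_parties

    return simulate_parties(SimSpec(seed=42))


@pytest.fixture
def pooled(small_parties):
    X = np.vstack([p.X for p in small_parties])
    y = np.concatenate([p.y for p in small_parties])
    return X, y
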