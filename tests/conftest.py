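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
    return np.random.default_rng(12345)


@pytest.fixture
def equicorr():
    """Factory for p x p equicorrelated correlation matrices."""
    from efagrid import CorrelationMatrix

    def make(p, r):
        return CorrelationMatrix(np.where(np.eye(p, dtype=bool), 1.0, r))

    return make
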