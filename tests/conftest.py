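import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "derandomized",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")

from enhancer_runaway import ModelParams


@pytest.fixture
def params_strong():
    """Strong-selection two-allele setting (s=0.1, h=0.25, u=1e-3)."""
    return ModelParams(s_mean=0.1, h=0.25, u_gene=1e-3, r=1e-6, N_pop=1000, seed=0)


@pytest.fixture
def params_weak():
    """Weak-selection setting (s=0.01)."""
    return ModelParams(s_mean=0.01, h=0.25, u_gene=1e-3, r=1e-6, N_pop=1000, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
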