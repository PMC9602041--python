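import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spikeplane.network import NetworkConfig
from spikeplane.plasticity import PlasticityParams

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
def small_net():
    """100-neuron network preserving the 4:1 population ratio and the 0.05
    connection probability of the full model."""
    return NetworkConfig(n_total=100, n_exc=80, n_inh=20, m_out=5)


@pytest.fixture
def stdp_params():
    return PlasticityParams()
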