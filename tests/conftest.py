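import numpy as np
import pytest

from trisynapse.config import NetworkConfig
from trisynapse.network import build_network

#: ~55-neuron reference layout used by simulator-level tests
TINY_COUNTS = {
    "dg_granule": 25, "dg_mossy": 3, "dg_basket": 3, "dg_interneuron": 2,
    "ca3_pyramidal": 8, "ca3_basket": 1, "ca3_interneuron": 1,
    "ca1_pyramidal": 10, "ca1_basket": 1, "ca1_interneuron": 1,
}


def tiny_config() -> NetworkConfig:
    cfg = NetworkConfig()
    cfg.counts = dict(TINY_COUNTS)
    # densify so the miniature network is actually connected
    from trisynapse.config import ConnectivityRule
    cfg.projections = [
        ConnectivityRule(r.source, r.target, min(1.0, r.p * 8),
                         r.weight_mean, r.weight_sd)
        for r in cfg.projections
    ]
    return cfg


@pytest.fixture(scope="session")
def tiny_net():
    return build_network(tiny_config(), scale=1.0, seed=7)


@pytest.fixture(scope="session")
def small_net():
    """1/20-scale hippocampal network (~440 neurons)."""
    return build_network(scale=0.05, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
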