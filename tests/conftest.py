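import numpy as np
import pytest

from vtanet import build_network
from vtanet.network import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def net():
    return build_network(NetworkConfig(), rng=42)


def settle(net, n_steps=1000, learning_on=False):
    """Run the network without stimuli for n_steps; returns VTA rate trace."""
    cs = np.zeros(3)
    us = np.zeros(4)
    out = np.empty(n_steps)
    for i in range(n_steps):
        net.step(cs, us, 0.0, learning_on)
        out[i] = net.r_vta
    return out
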