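import numpy as np
import pytest

from tumoroxy.core import SimConfig
from tumoroxy.hemodynamics import solve_hemodynamics
from tumoroxy.netgen import generate_initial_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale configuration: a 1.6 mm box resolves a few hundred
    lattice cells yet generates in seconds."""
    return SimConfig(root_geometry="RC1", L=1640.0, seed=7)


@pytest.fixture(scope="session")
def small_net(small_config):
    """One shared small t=0 network with converged hemodynamics."""
    net = generate_initial_network(small_config)
    solve_hemodynamics(net, small_config.hemo)
    return net
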