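import numpy as np
import pytest

from caclandscape import find_attractors, load_cac_network, make_toy


@pytest.fixture(scope="session")
def toggle():
    return make_toy("toggle_switch")


@pytest.fixture(scope="session")
def toggle_attractors(toggle):
    aset = find_attractors(toggle, n_starts=60, seed=1)
    assert aset.n_stable == 2
    return aset


@pytest.fixture(scope="session")
def double_well():
    return make_toy("double_well_1d")


@pytest.fixture(scope="session")
def dw_attractors(double_well):
    aset = find_attractors(double_well, n_starts=30, seed=2)
    assert aset.n_stable == 2
    # order: left well first
    aset.points.sort(key=lambda p: p.state[0])
    return aset


@pytest.fixture(scope="session")
def cac():
    """Packaged cancer-adipose conversion network (synthetic reconstruction)."""
    return load_cac_network()


@pytest.fixture(scope="session")
def cac_five_state():
    """The five-attractor condition: moderate TGF-beta plus MEKi and Rosi."""
    net = load_cac_network(TGFB=4.3, MEKI=0.02, ROSI=1.5)
    aset = find_attractors(net, n_starts=200, seed=7, include_unstable=False)
    return net, aset
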