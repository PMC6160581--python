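import numpy as np
import pytest

from coshnet.network import CapillaryNetwork, NetworkNode, Vessel
from coshnet.params import OxygenParameters, SolverSettings
from coshnet.synthetic import NetworkStatsTarget, generate_network, \
    assign_reference_flow


def straight(p0, p1):
    return np.array([p0, p1], dtype=float)


def make_chain(n_vessels=3, length=100.0, diameter=5.0, v_rbc=1000.0,
               H_T=0.25):
    """A straight chain of vessels with uniform assigned flow state."""
    nodes = {}
    vessels = {}
    for i in range(n_vessels + 1):
        kind = "inflow" if i == 0 else ("outflow" if i == n_vessels else "interior")
        nodes[i] = NetworkNode(i, [i * length, 0.0, 0.0], boundary_kind=kind)
    for i in range(n_vessels):
        vessels[i] = Vessel(i, i, i + 1,
                            straight([i * length, 0, 0], [(i + 1) * length, 0, 0]),
                            diameter)
    net = CapillaryNetwork(vessels, nodes)
    net.derive_radii()
    for v in net.vessels.values():
        v.v_rbc = v_rbc
        v.q = v_rbc * v.lumen_area
        v.H_T = H_T
        v.mu_LD = H_T / 0.64
        v.q_rbc = v.q * H_T
    return net


def make_converging_y(v_parent=(1000.0, 1000.0), H_T=0.25, length=100.0,
                      diameter=5.0):
    """Two inflow parents converging into one outflow child."""
    L = length
    nodes = {
        0: NetworkNode(0, [0, -50, 0], boundary_kind="inflow"),
        1: NetworkNode(1, [0, 50, 0], boundary_kind="inflow"),
        2: NetworkNode(2, [L, 0, 0], boundary_kind="interior"),
        3: NetworkNode(3, [2 * L, 0, 0], boundary_kind="outflow"),
    }
    vessels = {
        0: Vessel(0, 0, 2, straight([0, -50, 0], [L, 0, 0]), diameter),
        1: Vessel(1, 1, 2, straight([0, 50, 0], [L, 0, 0]), diameter),
        2: Vessel(2, 2, 3, straight([L, 0, 0], [2 * L, 0, 0]), diameter),
    }
    net = CapillaryNetwork(vessels, nodes)
    net.derive_radii()
    for vid, v in net.vessels.items():
        vv = v_parent[vid] if vid < 2 else sum(v_parent)
        v.v_rbc = vv
        v.q = vv * v.lumen_area
        v.H_T = H_T
        v.mu_LD = H_T / 0.64
        v.q_rbc = v.q * H_T
    return net


@pytest.fixture
def chain3():
    return make_chain(3)


@pytest.fixture
def params():
    return OxygenParameters()


@pytest.fixture
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def _solved_net_cached():
    stats = NetworkStatsTarget.mouse_cortex_1_sub()
    rng = np.random.default_rng(7)
    net = generate_network(stats, seed=rng)
    assign_reference_flow(net, stats, seed=rng)
    return net, stats


@pytest.fixture
def solved_net(_solved_net_cached):
    """A published-statistics synthetic network with reference flow.

    Handed out as a deep copy: several consumers (reconstruction, hematocrit
    redistribution) mutate the flow state in place."""
    import copy
    net, stats = _solved_net_cached
    return copy.deepcopy(net), stats
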