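import itertools

import numpy as np
import networkx as nx
import pytest

from coshnet.network import CapillaryNetwork, NetworkNode, Vessel
from coshnet.metrics import (enumerate_paths, integrate_paths, weighted_mean,
                             weighted_sd, weighted_cov, compare_models,
                             correlation_suite, PathRecord)
from conftest import make_chain, make_converging_y, straight


def make_diamond(v_in=1000.0, n_branches=2):
    """Inflow → diverging node → n parallel branches → converging → outflow."""
    L = 100.0
    nodes = {0: NetworkNode(0, [0, 0, 0], boundary_kind="inflow"),
             1: NetworkNode(1, [L, 0, 0])}
    vessels = {}
    mk = lambda vid, a, b: Vessel(vid, a, b, straight(nodes[a].position,
                                                      nodes[b].position), 5.0)
    last = 2 + n_branches
    for k in range(n_branches):
        nodes[2 + k] = NetworkNode(2 + k, [2 * L, 60 * k - 30 * (n_branches - 1),
                                           0])
    nodes[last] = NetworkNode(last, [3 * L, 0, 0])
    nodes[last + 1] = NetworkNode(last + 1, [4 * L, 0, 0],
                                  boundary_kind="outflow")
    vessels[0] = mk(0, 0, 1)
    for k in range(n_branches):
        vessels[1 + 2 * k] = mk(1 + 2 * k, 1, 2 + k)
        vessels[2 + 2 * k] = mk(2 + 2 * k, 2 + k, last)
    out_id = 1 + 2 * n_branches
    vessels[out_id] = mk(out_id, last, last + 1)
    net = CapillaryNetwork(vessels, nodes)
    net.derive_radii()
    for vid, v in net.vessels.items():
        vv = v_in if vid in (0, out_id) else v_in / n_branches
        v.v_rbc = vv
        v.q = vv * v.lumen_area
        v.H_T = 0.25
        v.mu_LD = 0.25 / 0.64
        v.q_rbc = v.q * 0.25
    return net


class TestWeightedStats:
    def test_equal_weights_sd(self):
        assert weighted_sd([0.4, 0.6], [1, 1]) == pytest.approx(0.1)

    def test_all_equal_zero_sd(self):
        assert weighted_sd([0.5, 0.5, 0.5], [1, 2, 3]) == 0.0

    def test_hand_arithmetic(self):
        # weights (2, 1) on (0.3, 0.6): mean 0.4, SD sqrt(0.02)
        assert weighted_mean([0.3, 0.6], [2, 1]) == pytest.approx(0.4)
        assert weighted_sd([0.3, 0.6], [2, 1]) == pytest.approx(np.sqrt(0.02))

    def test_zero_weight_sum_rejected(self):
        with pytest.raises(ValueError):
            weighted_sd([1.0], [0.0])


class TestEnumeratePaths:
    def test_single_chain(self):
        net = make_chain(3)
        paths = enumerate_paths(net)
        assert len(paths) == 1
        assert paths[0].weight == pytest.approx(1.0)
        assert paths[0].vessels == (0, 1, 2)
        tau = sum(net.vessels[v].length / abs(net.vessels[v].v_rbc)
                  for v in (0, 1, 2))
        assert paths[0].transit_time == pytest.approx(tau)

    def test_symmetric_diamond(self):
        net = make_diamond()
        paths = enumerate_paths(net)
        assert len(paths) == 2
        assert sorted(p.weight for p in paths) == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("seed", range(4))
    def test_weights_sum_to_one_vs_exhaustive(self, seed):
        # brute-force oracle: enumerate simple paths on small random nets
        from coshnet.synthetic import (NetworkStatsTarget, generate_network,
                                       assign_reference_flow)
        stats = NetworkStatsTarget(n_vessels=12, bounding_box=(120, 120, 100),
                                   n_converging=3)
        net = generate_network(stats, seed=seed)
        assign_reference_flow(net, stats, seed=seed + 50)
        paths = enumerate_paths(net)
        assert sum(p.weight for p in paths) == pytest.approx(1.0, abs=1e-9)
        # oracle: networkx all_simple_edge_paths between boundary nodes,
        # over the RBC-carrying subgraph (zero-RBC-flux branches carry no
        # path weight and are not enumerated)
        dg = net.directed_graph()
        for vid, v in net.vessels.items():
            if v.q != 0.0 and v.q_rbc == 0.0:
                dg.remove_edge(v.upstream_node(), v.downstream_node(), key=vid)
        count = 0
        sources = {net.vessels[v].upstream_node() for v in net.inflow_vessels()
                   if net.vessels[v].q != 0.0}
        sinks = {net.vessels[v].downstream_node() for v in net.outflow_vessels()
                 if net.vessels[v].q != 0.0}
        for s, t in itertools.product(sources, sinks):
            count += sum(1 for _ in nx.all_simple_edge_paths(dg, s, t))
        assert len(paths) == count


class TestCompareModels:
    def test_identical_sets_zero_reduction(self):
        out = compare_models(0.08, 0.08, 0.08)
        assert out["reduction_percent"] == 0.0

    def test_printed_reduction_arithmetic(self):
        # σ 0.0891 → 0.0512 is a 42.5% reduction
        out = compare_models(0.0891, 0.0599, 0.0512)
        assert out["reduction_percent"] == pytest.approx(42.54, abs=0.01)
        assert 0 < out["capillary_share"] < 1
        assert out["capillary_share"] + out["rbc_share"] == pytest.approx(1.0)

    def test_invalid_geometric(self):
        with pytest.raises(ValueError):
            compare_models(0.0, 0.0, 0.0)


class TestCorrelationSuite:
    def _records(self, tau, dS, S_a=0.6):
        n = len(tau)
        return [PathRecord((i,), 1.0 / n, tau[i], 100.0 * tau[i] * 10,
                           S_a, S_a - dS[i]) for i in range(n)]

    def test_perfect_linear_pair(self):
        tau = np.linspace(0.05, 0.4, 30)
        recs = self._records(tau, 0.3 * tau)
        s = correlation_suite(recs)
        r, p = s.correlations["dS_transit"]
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-20

    def test_independent_noise_is_uncorrelated(self):
        rng = np.random.default_rng(12)
        tau = rng.uniform(0.05, 0.4, 100)
        recs = self._records(tau, rng.uniform(0.01, 0.3, 100))
        s = correlation_suite(recs)
        assert abs(s.correlations["dS_transit"][0]) < 0.3

    @staticmethod
    def _three_branch_unequal():
        net = make_diamond(v_in=900.0, n_branches=3)
        for vid, vv in ((1, 200.0), (3, 400.0), (5, 800.0)):
            v = net.vessels[vid]
            v.v_rbc = vv
            v.q = vv * v.lumen_area
            v.q_rbc = v.q * 0.25
        return net

    def test_ode_linear_limit_r_equals_one(self, params, settings):
        # uniform hematocrit and shared extraction with α_eff → 0 make ΔS a
        # linear function of transit time alone
        net = self._three_branch_unequal()
        p = params.replace(alpha_eff=1e-300)
        paths = enumerate_paths(net)
        radii = {vid: 10.0 for vid in net.vessels}
        integrate_paths(net, paths, {0: 0.6}, radii, p, settings)
        s = correlation_suite(paths)
        assert s.correlations["dS_transit"][0] == pytest.approx(1.0, abs=1e-6)

    def test_cov_equality_in_linear_limit(self, params, settings):
        # same setting: CoV(ΔS) equals CoV(τ) when ΔS ∝ τ
        net = self._three_branch_unequal()
        p = params.replace(alpha_eff=1e-300)
        paths = enumerate_paths(net)
        integrate_paths(net, paths, {0: 0.6}, {vid: 10.0 for vid in net.vessels},
                        p, settings)
        s = correlation_suite(paths)
        assert s.cov_dS == pytest.approx(s.cov_transit, rel=1e-3)

    def test_reduction_invariant_under_weight_rescale(self):
        tau = np.linspace(0.05, 0.4, 20)
        recs = self._records(tau, 0.2 * tau)
        a = correlation_suite(recs)
        for r in recs:
            r.weight *= 3.0
        b = correlation_suite(recs)
        assert a.cosh == pytest.approx(b.cosh)
        assert a.cov_dS == pytest.approx(b.cov_dS)
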