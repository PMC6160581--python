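import numpy as np
import pytest

from coshnet.network import (CapillaryNetwork, NetworkNode, Vessel,
                             NetworkParseError, NetworkValidationError,
                             load_network, save_network)
from conftest import make_chain, make_converging_y, straight


def test_minimal_two_node_network():
    nodes = {0: NetworkNode(0, [0, 0, 0], boundary_kind="inflow"),
             1: NetworkNode(1, [100, 0, 0], boundary_kind="outflow")}
    vessels = {0: Vessel(0, 0, 1, straight([0, 0, 0], [100, 0, 0]), 5.0)}
    net = CapillaryNetwork(vessels, nodes)
    net.validate()
    assert net.n_vessels == 1
    assert all(net.nodes[n].is_boundary for n in net.nodes)


def test_arc_length_matches_polyline():
    cl = np.array([[0, 0, 0], [30, 40, 0], [30, 40, 50.0]])
    v = Vessel(0, 0, 1, cl, 5.0)
    assert v.length == pytest.approx(50.0 + 50.0, rel=1e-12)


@pytest.mark.parametrize("fmt,suffix", [("json", "net.json"), ("csv", "net.csv")])
def test_save_load_round_trip(tmp_path, fmt, suffix):
    net = make_chain(3)
    path = tmp_path / suffix
    save_network(net, path, format=fmt)
    loaded = load_network(path, format=fmt)
    assert loaded.n_vessels == net.n_vessels
    for vid, v in net.vessels.items():
        lv = loaded.vessels[vid]
        np.testing.assert_array_equal(lv.centerline, v.centerline)
        assert lv.diameter == v.diameter
        assert lv.q == pytest.approx(v.q)
        assert lv.H_T == pytest.approx(v.H_T)
    for nid, n in net.nodes.items():
        assert loaded.nodes[nid].boundary_kind == n.boundary_kind
        np.testing.assert_array_equal(loaded.nodes[nid].position, n.position)


def test_unknown_node_reference_raises():
    nodes = {0: NetworkNode(0, [0, 0, 0])}
    vessels = {0: Vessel(0, 0, 99, straight([0, 0, 0], [1, 0, 0]), 5.0)}
    with pytest.raises(NetworkParseError, match="99"):
        CapillaryNetwork(vessels, nodes)


def test_duplicate_ids_raise():
    payload = {
        "bounding_box": [[0, 0, 0], [1, 1, 1]],
        "nodes": [{"id": 0, "position": [0, 0, 0], "boundary_kind": "inflow"},
                  {"id": 0, "position": [1, 0, 0], "boundary_kind": "outflow"}],
        "vessels": [],
    }
    with pytest.raises(NetworkParseError, match="duplicate"):
        CapillaryNetwork.from_dict(payload)


def test_disconnected_network_rejected():
    nodes = {i: NetworkNode(i, [i * 10.0, 0, 0],
                            boundary_kind="inflow" if i % 2 == 0 else "outflow")
             for i in range(4)}
    vessels = {0: Vessel(0, 0, 1, straight([0, 0, 0], [10, 0, 0]), 5.0),
               1: Vessel(1, 2, 3, straight([20, 0, 0], [30, 0, 0]), 5.0)}
    net = CapillaryNetwork(vessels, nodes)
    with pytest.raises(NetworkValidationError, match="disconnected"):
        net.validate()


def test_missing_file_raises(tmp_path):
    with pytest.raises(NetworkParseError, match="no such file"):
        load_network(tmp_path / "nope.json")


class TestRescaleDiameters:
    def test_already_on_target_unchanged(self):
        net = make_chain(4)
        target = np.array([v.diameter for v in net.vessels.values()])
        # diameters 5, sd 0 would be degenerate; build a spread instead
        for v, d in zip(net.vessels.values(), [3.5, 4.5, 5.5, 6.5]):
            v.diameter = d
        d0 = np.array([v.diameter for v in net.vessels.values()])
        net.rescale_diameters(target_mean=d0.mean(), target_sd=d0.std(), floor=3.0)
        d1 = np.array([v.diameter for v in net.vessels.values()])
        np.testing.assert_allclose(d1, d0, rtol=1e-12)

    def test_floor_enforced(self):
        net = make_chain(6)
        for v, d in zip(net.vessels.values(), [2.0, 3.0, 4.0, 5.0, 8.0, 12.0]):
            v.diameter = d
        net.rescale_diameters(target_mean=5.0, target_sd=1.5, floor=3.0)
        assert all(v.diameter >= 3.0 for v in net.vessels.values())

    def test_constant_input_maps_to_target_mean(self):
        net = make_chain(3)
        for v in net.vessels.values():
            v.diameter = 4.0
        with pytest.warns(UserWarning):
            net.rescale_diameters(target_mean=5.0, target_sd=1.5, floor=3.0)
        assert all(v.diameter == pytest.approx(5.0) for v in net.vessels.values())

    def test_length_invariant_under_rescaling(self):
        net = make_chain(4)
        for v, d in zip(net.vessels.values(), [3.5, 4.5, 5.5, 6.5]):
            v.diameter = d
        total = sum(v.length for v in net.vessels.values())
        net.rescale_diameters()
        assert sum(v.length for v in net.vessels.values()) == pytest.approx(total)


class TestDeriveRadii:
    @pytest.mark.parametrize("d,r_c,r_w", [
        (4.0, 1.6, 2.5),       # r_p = 2.0: plain ratios
        (10.0, 4.0, 6.25),     # RBC diameter clamped at 8 → r_c = 4
        (3.0, 1.5, 1.875),     # 0.8·1.5 = 1.2 < 1.5 → clamped up to 1.5
    ])
    def test_radius_rules(self, d, r_c, r_w):
        net = make_chain(1, diameter=d)
        net.derive_radii()
        v = net.vessels[0]
        assert v.r_p == pytest.approx(d / 2)
        assert v.r_c == pytest.approx(r_c)
        assert v.r_w == pytest.approx(r_w)


class TestClassifyBifurcations:
    def test_converging_y(self):
        net = make_converging_y()
        labels = net.classify_bifurcations()
        assert labels[2] == "after_converging"
        assert labels[0] == "inflow" and labels[1] == "inflow"
        assert net.n_converging_bifurcations() == 1

    def test_chain_has_none(self):
        net = make_chain(3)
        labels = net.classify_bifurcations()
        assert "after_converging" not in labels.values()
        assert net.n_converging_bifurcations() == 0

    def test_zero_flow_vessel_is_other(self):
        net = make_chain(3)
        net.vessels[1].q = 0.0
        assert net.classify_bifurcations()[1] == "other"

    def test_counts_match_brute_force(self, solved_net):
        net, _ = solved_net
        # brute force over interior nodes
        count = 0
        for node in net.nodes.values():
            if node.is_boundary:
                continue
            indeg = sum(1 for vid in node.vessel_ids
                        if net.vessels[vid].q != 0.0
                        and np.isfinite(net.vessels[vid].q)
                        and net.vessels[vid].downstream_node() == node.id)
            count += indeg >= 2
        assert net.n_converging_bifurcations() == count
        labels = net.classify_bifurcations()
        after = [vid for vid, lab in labels.items() if lab == "after_converging"]
        # every after-converging vessel's upstream node has in-degree ≥ 2
        for vid in after:
            node = net.nodes[net.vessels[vid].upstream_node()]
            indeg = sum(1 for k in node.vessel_ids
                        if net.vessels[k].q != 0.0
                        and net.vessels[k].downstream_node() == node.id)
            assert indeg >= 2


def test_vtk_export_writes_polydata(tmp_path):
    net = make_chain(2)
    out = tmp_path / "net.vtk"
    net.to_vtk(out)
    text = out.read_text()
    assert "DATASET POLYDATA" in text
    assert "LINES 2" in text
    assert "SCALARS diameter" in text
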