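import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from coshnet.params import OxygenParameters, SolverSettings
from coshnet.oxygen import (hill_peq, hill_seq, hill_dpeq_ds,
                            convective_capacity, extraction_rate,
                            SaturationDistribution, integrate_vessel,
                            propagate_network, oxygen_balance)
from coshnet.flow import solve_pressures
from conftest import make_chain, make_converging_y


class TestHill:
    def test_midpoint_identity(self):
        assert hill_peq(0.5, P50=47.9, hill_n=2.64) == pytest.approx(47.9)

    def test_inverse_identity(self):
        s = 0.73
        assert hill_seq(hill_peq(s)) == pytest.approx(s, abs=1e-12)

    def test_formula_value(self):
        # S = 0.8 → P = P50 · 4^(1/n), evaluated independently
        expected = 47.9 * 4.0 ** (1.0 / 2.64)
        assert hill_peq(0.8, P50=47.9, hill_n=2.64) == pytest.approx(expected)

    def test_derivative_matches_finite_difference(self):
        s, h = 0.62, 1e-7
        fd = (hill_peq(s + h) - hill_peq(s - h)) / (2 * h)
        assert hill_dpeq_ds(s) == pytest.approx(fd, rel=1e-6)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @hsettings(max_examples=50, deadline=None)
    def test_inverse_round_trip_property(self, s):
        assert hill_seq(hill_peq(s)) == pytest.approx(s, abs=1e-10)


class TestCapacityExtraction:
    def test_alpha_zero_limit(self, params):
        net = make_chain(1, v_rbc=1000.0)
        v = net.vessels[0]
        v.mu_LD = 0.3906
        p = params.replace(alpha_eff=1e-300)
        expected = 1000.0 * 0.3906 * np.pi * v.r_c**2 * 0.5
        got = convective_capacity(0.5, v, p)
        assert got == pytest.approx(expected, rel=1e-6)
        # and independent of S in this limit
        assert convective_capacity(0.2, v, p) == pytest.approx(got, rel=1e-6)

    def test_linear_in_velocity(self, params):
        net = make_chain(1)
        v = net.vessels[0]
        q1 = convective_capacity(0.5, v, params)
        v.v_rbc *= 2
        assert convective_capacity(0.5, v, params) == pytest.approx(2 * q1)

    def test_extraction_examples(self):
        assert extraction_rate(2.5, 2.5, 1.0) == 0.0
        expected = np.pi * (18.8**2 - 2.5**2)
        assert extraction_rate(18.8, 2.5, 1.0) == pytest.approx(expected)
        rates = [extraction_rate(r, 2.5, 1.0) for r in (5, 10, 20, 40)]
        assert np.all(np.diff(rates) > 0)
        with pytest.raises(ValueError):
            extraction_rate(2.0, 2.5, 1.0)


class TestSaturationDistribution:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SaturationDistribution(np.array([0.5]), np.array([0.9]))

    def test_merge_conserves_mean_and_cap(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(0.2, 0.8, 50)
        w = rng.dirichlet(np.ones(50))
        d = SaturationDistribution(S, w)
        m = d.merged(8)
        assert len(m.S) == 8
        assert m.w.sum() == pytest.approx(1.0, abs=1e-12)
        assert m.mean == pytest.approx(d.mean, abs=1e-9)


class TestIntegrateVessel:
    def test_alpha_zero_closed_form(self, params, settings):
        net = make_chain(1, v_rbc=1000.0, length=100.0)
        v = net.vessels[0]
        p = params.replace(alpha_eff=1e-300)
        jt = 10.0  # small enough that S never floors over the vessel
        prof = integrate_vessel(SaturationDistribution.delta(0.6), v, jt, p,
                                settings)
        slope = jt / (1000.0 * v.mu_LD * np.pi * v.r_c**2 * p.C0)
        expected = 0.6 - slope * prof.x
        np.testing.assert_allclose(prof.S_atoms[0], expected, atol=1e-8)

    def test_zero_extraction_conserves(self, params, settings):
        net = make_chain(1)
        prof = integrate_vessel(SaturationDistribution.delta(0.6),
                                net.vessels[0], 0.0, params, settings)
        np.testing.assert_allclose(prof.S_atoms[0], 0.6, atol=1e-12)

    def test_floor_reached_is_flagged(self, params, settings):
        net = make_chain(1, v_rbc=100.0, length=200.0)
        prof = integrate_vessel(SaturationDistribution.delta(0.05),
                                net.vessels[0], 2000.0, params, settings)
        assert prof.floored[0]
        assert prof.S_atoms[0, -1] == 0.0
        # monotone non-increasing everywhere
        assert np.all(np.diff(prof.S_atoms[0]) <= 1e-12)


class TestPropagateNetwork:
    def _radii(self, net, r_t=18.8):
        return {vid: r_t for vid in net.vessels}

    def test_equal_flux_merge_weights(self, params, settings):
        net = make_converging_y()
        res = propagate_network(net, {0: 0.6, 1: 0.4}, self._radii(net),
                                params.replace(M0=1e-300), settings)
        inlet = res.inlet[2]
        np.testing.assert_allclose(sorted(inlet.w), [0.5, 0.5])
        np.testing.assert_allclose(sorted(inlet.S), [0.4, 0.6])

    def test_flux_weighted_merge_2_to_1(self, params, settings):
        net = make_converging_y(v_parent=(2000.0, 1000.0))
        res = propagate_network(net, {0: 0.6, 1: 0.4}, self._radii(net),
                                params.replace(M0=1e-300), settings)
        inlet = res.inlet[2]
        w = dict(zip(inlet.S.round(6), inlet.w))
        assert w[0.6] == pytest.approx(2 / 3)
        assert w[0.4] == pytest.approx(1 / 3)

    def test_chain_single_atom(self, params, settings):
        net = make_chain(3)
        res = propagate_network(net, {0: 0.6}, self._radii(net), params,
                                settings)
        assert all(len(res.profiles[vid].w) == 1 for vid in res.profiles)

    def test_atom_weights_always_sum_to_one(self, params, settings, solved_net):
        net, _ = solved_net
        inflow_S = {vid: 0.6 for vid in net.inflow_vessels()}
        res = propagate_network(net, inflow_S, self._radii(net), params,
                                settings)
        for vid, prof in res.profiles.items():
            assert prof.w.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.outflow_w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_saturation(self, params, settings, solved_net):
        net, _ = solved_net
        inflow_S = {vid: 0.6 for vid in net.inflow_vessels()}
        res = propagate_network(net, inflow_S, self._radii(net, 10.0), params,
                                settings)
        for prof in res.profiles.values():
            assert np.all(np.diff(prof.S_atoms, axis=1) <= 1e-9)

    def test_oxygen_balance_without_floors(self, params, settings, solved_net):
        # low consumption keeps every atom off the floor; the released
        # oxygen must equal the prescribed consumption
        net, _ = solved_net
        p = params.replace(M0=1e-4)
        inflow_S = {vid: 0.6 for vid in net.inflow_vessels()}
        radii = self._radii(net)
        res = propagate_network(net, inflow_S, radii, p, settings)
        bal = oxygen_balance(net, res, radii, p)
        assert not bal["floored_vessels"]
        assert bal["relative_error"] < 1e-3

    def test_mean_outflow_invariant_to_radii_source(self, params, settings,
                                                    solved_net):
        # total extraction, hence mean outflow S, depends only on the total
        # tissue volume when no atom floors — redistributing radii while
        # keeping the total constant leaves the mean (nearly) unchanged
        net, _ = solved_net
        p = params.replace(M0=1e-4)
        inflow_S = {vid: 0.6 for vid in net.inflow_vessels()}
        res_a = propagate_network(net, inflow_S, self._radii(net, 18.8), p,
                                  settings)
        rng = np.random.default_rng(1)
        radii_b = {}
        ids = list(net.vessels)
        for vid in ids:
            radii_b[vid] = 18.8 * rng.uniform(0.7, 1.3)
        # rescale so the total tissue volume matches the uniform case
        va = sum(net.vessels[v].length * np.pi *
                 (18.8**2 - net.vessels[v].r_w**2) for v in ids)
        vb = sum(net.vessels[v].length * np.pi *
                 (radii_b[v]**2 - net.vessels[v].r_w**2) for v in ids)
        scale = np.sqrt(va / vb)
        radii_b = {v: max(r * scale, net.vessels[v].r_w) for v, r in radii_b.items()}
        res_b = propagate_network(net, inflow_S, radii_b, p, settings)
        assert res_b.mean_outflow == pytest.approx(res_a.mean_outflow, abs=0.01)
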