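import numpy as np
import pytest

from coshnet.rheology import (vessel_resistance, relative_viscosity_in_vivo,
                              linear_density, phase_separation_fractions,
                              PLASMA_VISCOSITY_MPAS, MMHG_PER_PA)
from coshnet.flow import (solve_pressures, distribute_hematocrit,
                          conservation_residuals, FlowReconstruction)
from coshnet.synthetic import (NetworkStatsTarget, generate_network,
                               assign_reference_flow, sample_measurements)
from conftest import make_chain, make_converging_y


class TestResistance:
    def test_linear_in_length(self):
        assert vessel_resistance(5.0, 100.0, 0.25) == pytest.approx(
            2 * vessel_resistance(5.0, 50.0, 0.25))

    def test_d4_law_lower_bound(self):
        # halving d multiplies R by ≥ 16 (viscosity also rises at small d)
        r1 = vessel_resistance(8.0, 100.0, 0.25)
        r2 = vessel_resistance(4.0, 100.0, 0.25)
        assert r2 / r1 >= 16.0

    def test_zero_hematocrit_reduces_to_plasma_formula(self):
        # independent evaluation of the H_T = 0 limit from the viscosity law
        d, L = 5.0, 80.0
        mu = PLASMA_VISCOSITY_MPAS * 1e-3 * relative_viscosity_in_vivo(d, 0.0)
        expected = 128.0 * mu * L / (np.pi * d**4) * MMHG_PER_PA
        assert vessel_resistance(d, L, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_hematocrit(self):
        r = [vessel_resistance(5.0, 100.0, h) for h in (0.0, 0.2, 0.4, 0.6)]
        assert np.all(np.diff(r) > 0)


class TestLinearDensity:
    def test_algebra_from_definitions(self):
        # H_T = 0.25, r_c = 0.8 r_p → μ = 0.25 / 0.64
        assert linear_density(0.25, 2.0, 1.6) == pytest.approx(0.25 / 0.64)

    def test_zero(self):
        assert linear_density(0.0, 2.0, 1.6) == 0.0

    def test_boundary_clip(self):
        assert linear_density(0.64, 2.0, 1.6) == pytest.approx(1.0)
        assert linear_density(0.8, 2.0, 1.6) == 1.0  # clipped

    def test_invalid_hematocrit(self):
        with pytest.raises(ValueError):
            linear_density(1.0, 2.0, 1.6)


class TestSolvePressures:
    def test_single_vessel_ohm_analogy(self):
        net = make_chain(1)
        R = vessel_resistance(net.vessels[0].diameter, net.vessels[0].length,
                              0.25)
        res = solve_pressures(net, {0: 10.0 + R * 1.0, 1: 10.0})
        assert net.vessels[0].q == pytest.approx(1.0, rel=1e-6)

    def test_symmetric_y_equal_flows(self):
        net = make_converging_y()
        res = solve_pressures(net, {0: 50.0, 1: 50.0, 3: 10.0})
        assert net.vessels[0].q == pytest.approx(net.vessels[1].q, rel=1e-10)

    def test_conservation_contract(self, solved_net):
        net, _ = solved_net
        cons = conservation_residuals(net)
        assert cons["volume"] < 1e-10
        assert cons["rbc_flux"] < 1e-10

    def test_gauge_invariance(self):
        net = make_converging_y()
        solve_pressures(net, {0: 50.0, 1: 45.0, 3: 10.0})
        q0 = [v.q for v in net.vessels.values()]
        solve_pressures(net, {0: 150.0, 1: 145.0, 3: 110.0})
        q1 = [v.q for v in net.vessels.values()]
        np.testing.assert_allclose(q1, q0, rtol=1e-9)


class TestDistributeHematocrit:
    def test_chain_conserves_inflow_value(self):
        net = make_chain(4)
        solve_pressures(net, {0: 20.0, 4: 10.0}, inflow_H_T=0.25)
        assert all(v.H_T == pytest.approx(0.25, rel=1e-9)
                   for v in net.vessels.values())

    def test_symmetric_diverging_equal_children(self):
        # reversed Y: one inflow splits into two equal outflows
        net = make_converging_y()
        solve_pressures(net, {0: 10.0, 1: 10.0, 3: 40.0}, inflow_H_T=0.25)
        # now vessel 2 is the parent; 0 and 1 are children
        assert net.vessels[0].H_T == pytest.approx(net.vessels[1].H_T, rel=1e-9)

    def test_phase_separation_fractions_sum_to_one(self):
        frac = phase_separation_fractions([2.0, 1.0], [5.0, 4.0], 5.0, 0.3)
        assert frac.sum() == pytest.approx(1.0)
        assert np.all(frac >= 0)

    def test_rich_branch_gets_disproportionate_flux(self):
        # the empirical law sends RBCs preferentially into the faster branch
        frac = phase_separation_fractions([3.0, 1.0], [5.0, 5.0], 5.0, 0.3)
        assert frac[0] > 0.75


class TestReconstruction:
    def test_no_measurements_needs_drop_constraint(self, solved_net):
        net, stats = solved_net
        rec = FlowReconstruction(net, [], inflow_H_T=0.25, dp_min=5.0)
        res = rec.fit()
        # the mean-drop constraint keeps the flow alive
        v = np.abs([x.v_rbc for x in net.vessels.values()])
        assert np.max(v) > 10.0
        drop = (np.mean([res.node_pressures[n] for n in net.boundary_nodes("inflow")])
                - np.mean([res.node_pressures[n] for n in net.boundary_nodes("outflow")]))
        assert drop >= 5.0 - 1e-6

    def test_full_noise_free_recovery(self):
        # self-consistency: exact complete measurements recover the truth
        stats = NetworkStatsTarget.mouse_cortex_1_sub()
        rng = np.random.default_rng(21)
        net = generate_network(stats, seed=rng)
        assign_reference_flow(net, stats, seed=rng)
        truth = {vid: abs(net.vessels[vid].v_rbc) for vid in net.vessels}
        meas = sample_measurements(net, fraction=1.0, noise_sd=0.0, seed=rng)
        FlowReconstruction(net, meas).fit()
        ids = [vid for vid in net.vessels if truth[vid] >= 1.0]
        vm = np.array([abs(net.vessels[vid].v_rbc) for vid in ids])
        vt = np.array([truth[vid] for vid in ids])
        rms = np.sqrt(np.mean(((vm - vt) / vt) ** 2))
        assert rms <= 0.02

    def test_all_zero_weights_rejected(self, solved_net):
        net, _ = solved_net
        meas = [(vid, abs(net.vessels[vid].v_rbc)) for vid in list(net.vessels)[:5]]
        with pytest.raises(ValueError, match="weights"):
            FlowReconstruction(net, meas, weights=np.zeros(5))

    def test_negative_measured_speed_rejected(self, solved_net):
        net, _ = solved_net
        with pytest.raises(ValueError, match="positive"):
            FlowReconstruction(net, [(0, -5.0)])
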