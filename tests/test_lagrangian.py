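import numpy as np
import pandas as pd
import pytest

from coshnet.params import OxygenParameters, SolverSettings
from coshnet.lagrangian import LagrangianModel, correlate_gap_vs_drop
from coshnet.oxygen import (propagate_network, hill_peq, extraction_rate,
                            SaturationDistribution, integrate_vessel)
from coshnet.territories import radius_from_volume, volume_from_radius
from conftest import make_chain, make_converging_y


def chain_volumes(net, r_t=18.8):
    return {vid: volume_from_radius(r_t, v.length, v.r_w)
            for vid, v in net.vessels.items()}


class TestInjection:
    @pytest.mark.parametrize("cv,tol", [(0.0, 0.02), (0.5, 0.05)])
    def test_realized_linear_density(self, params, settings, cv, tol):
        net = make_chain(1, length=400.0, v_rbc=1000.0, H_T=0.25)
        lm = LagrangianModel(net, {0: 0.6}, chain_volumes(net), params,
                             settings)
        res = lm.run(t_end=10.0, averaging_window=8.0, seed=3, spacing_cv=cv)
        df = res.vessel_transits[0]
        # realized linear density from the transit rate
        l_rbc = params.V_rbc / (np.pi * net.vessels[0].r_c**2)
        mu_real = len(df) / 8.0 * l_rbc / 1000.0
        assert mu_real == pytest.approx(net.vessels[0].mu_LD, rel=tol)

    def test_hard_core_no_overlap(self, params, settings):
        # back-to-back regime: inter-arrival times never below l_rbc / v
        net = make_chain(1, length=300.0, v_rbc=800.0, H_T=0.55)
        lm = LagrangianModel(net, {0: 0.6}, chain_volumes(net), params,
                             settings)
        res = lm.run(t_end=4.0, averaging_window=3.0, seed=1, spacing_cv=1.0)
        t_in = np.sort(res.vessel_transits[0]["t_in"].to_numpy())
        l_rbc = params.V_rbc / (np.pi * net.vessels[0].r_c**2)
        assert np.min(np.diff(t_in)) >= l_rbc / 800.0 - 1e-9


class TestStepPhysics:
    def test_tissue_decay_without_rbcs(self, params, settings):
        # no RBC supply: each bin's tension falls at rate M0/α_t to the floor
        net = make_chain(1, length=100.0, v_rbc=1000.0)
        lm = LagrangianModel(net, {0: 0.6}, chain_volumes(net), params,
                             settings, coupling=False)
        P = lm.P0.copy()
        rate = params.M0 / params.alpha_t
        dt = settings.dt
        for _ in range(100):
            P = np.maximum(P - rate * dt, 0.0)
        expected = np.maximum(lm.P0 - rate * 0.1, 0.0)
        np.testing.assert_allclose(P, expected, atol=1e-9)

    def test_equilibrium_rbc_keeps_saturation(self, params, settings):
        # when tissue tension equals the RBC equilibrium tension, no flux
        net = make_chain(1, length=300.0, v_rbc=1000.0)
        p0 = params.replace(M0=1e-12)  # negligible consumption
        lm = LagrangianModel(net, {0: 0.6}, chain_volumes(net), p0, settings,
                             coupling=False)
        lm.P0[:] = float(hill_peq(0.6, p0.P50, p0.hill_n))
        res = lm.run(t_end=2.0, averaging_window=1.0, seed=2, spacing_cv=0.0)
        out = res.path_records["S_out"]
        np.testing.assert_allclose(out, 0.6, atol=1e-4)

    def test_paired_rbc_interaction_reduces_difference(self, params, settings):
        # two trains with different S in one shared vessel: the saturation
        # difference must shrink downstream (RBC diffusive interaction)
        net = make_converging_y(v_parent=(900.0, 900.0), length=150.0)
        vols = chain_volumes(net)
        lm = LagrangianModel(net, {0: 0.7, 1: 0.5}, vols, params, settings)
        res = lm.run(t_end=6.0, averaging_window=2.0, seed=5, spacing_cv=0.3)
        st = res.vessel_stats()
        # the parents already exchange via shared tissue, so the inlet spread
        # is below the raw 0.1 mixture value but still substantial
        assert st.loc[2, "sigma_a"] > 0.03
        assert st.loc[2, "sigma_v"] < st.loc[2, "sigma_a"]


class TestRun:
    def test_deterministic_for_fixed_seed(self, params, settings):
        net = make_converging_y()
        vols = chain_volumes(net)
        a = LagrangianModel(net, {0: 0.6, 1: 0.6}, vols, params, settings) \
            .run(t_end=3.0, averaging_window=1.0, seed=11)
        b = LagrangianModel(net, {0: 0.6, 1: 0.6}, vols, params, settings) \
            .run(t_end=3.0, averaging_window=1.0, seed=11)
        pd.testing.assert_frame_equal(a.path_records, b.path_records)

    def test_cv0_matches_ode_on_single_path(self, params, settings):
        # uniform spacing, constant inflow: the particle model must converge
        # to the saturation-balance ODE with the same territory
        net = make_chain(3, length=150.0, v_rbc=900.0)
        r_t = 18.8
        vols = chain_volumes(net, r_t)
        lm = LagrangianModel(net, {0: 0.6}, vols, params, settings,
                             coupling=False)
        res = lm.run(t_end=10.0, averaging_window=2.0, seed=4, spacing_cv=0.0)
        s = 0.6
        for vid in (0, 1, 2):
            v = net.vessels[vid]
            jt = extraction_rate(r_t, v.r_w, params.M0)
            prof = integrate_vessel(SaturationDistribution.delta(s), v, jt,
                                    params, settings)
            s = float(prof.S_atoms[0, -1])
        got = res.path_records["S_out"].mean()
        assert abs(got - s) / (0.6 - s) <= 0.1  # within 10% of the total drop
        assert got == pytest.approx(s, abs=0.02)

    def test_oxygen_balance_closes(self, params, settings, solved_net):
        net, _ = solved_net
        from coshnet.territories import assign_geometric_territories
        _, vols = assign_geometric_territories(net, spacing=3.0)
        inflow_S = {vid: 0.6 for vid in net.inflow_vessels()}
        lm = LagrangianModel(net, inflow_S, vols, params, settings)
        res = lm.run(t_end=6.0, averaging_window=2.0, seed=8)
        assert res.o2_balance["relative_error"] < 0.01

    def test_no_exit_raises(self, params, settings):
        net = make_chain(1, length=400.0, v_rbc=1000.0)
        lm = LagrangianModel(net, {0: 0.6}, chain_volumes(net), params,
                             settings)
        with pytest.raises(RuntimeError, match="averaging window"):
            lm.run(t_end=0.01, averaging_window=0.005, seed=0)


class TestGapDropCorrelation:
    def test_constructed_positive_control(self):
        rng = np.random.default_rng(0)
        gaps = rng.exponential(0.01, 200)
        t_in = np.cumsum(gaps)
        drops = 2.0 * gaps + rng.normal(0, 0.002, 200)
        df = pd.DataFrame({"t_in": t_in, "S_in": 0.6,
                           "S_out": 0.6 - np.r_[0.0, drops[1:]],
                           "t_out": t_in + 0.05})
        out = correlate_gap_vs_drop(df, n_perm=300, seed=1)
        assert out["r"] > 0.5
        assert out["p_value"] < 0.05

    def test_null_behavior(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"t_in": np.cumsum(rng.exponential(0.01, 300)),
                           "S_in": 0.6,
                           "S_out": 0.5 + rng.normal(0, 0.01, 300),
                           "t_out": 0.0})
        out = correlate_gap_vs_drop(df, n_perm=300, seed=2)
        assert abs(out["r"]) < 0.2

    def test_degenerate_gaps_flagged(self):
        df = pd.DataFrame({"t_in": np.arange(50) * 0.01, "S_in": 0.6,
                           "S_out": 0.5, "t_out": 0.0})
        out = correlate_gap_vs_drop(df, n_perm=100, seed=0)
        assert out["degenerate"]

    def test_too_few_transits(self):
        df = pd.DataFrame({"t_in": [0, 1], "S_in": [0.6, 0.6],
                           "S_out": [0.5, 0.5], "t_out": [1, 2]})
        with pytest.raises(ValueError):
            correlate_gap_vs_drop(df)
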