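"""Network hydraulics: pressures, flows, hematocrit, and flow reconstruction.

Pressure-driven Poiseuille flow on the capillary graph with the Pries–Secomb
apparent viscosity closure and empirical phase separation at diverging
bifurcations. Unknown boundary conditions are reconstructed from sparse RBC
velocity measurements by minimizing dissipated hydraulic power plus a
weighted measurement misfit over the boundary pressures
(``FlowReconstruction`` / ``FlowResults``).

RBC velocity is identified with bulk velocity, v_rbc = q/(π r_p²); tube and
discharge hematocrit therefore coincide.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import CapillaryNetwork, NetworkValidationError
from .rheology import vessel_resistance, phase_separation_fractions, linear_density

__all__ = [
    "FlowConvergenceError",
    "FlowResults",
    "solve_pressures",
    "distribute_hematocrit",
    "conservation_residuals",
    "FlowReconstruction",
]

H_MAX = 0.95  # cap on child tube hematocrit during phase separation


class FlowConvergenceError(RuntimeError):
    def __init__(self, message: str, history: list[float] | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass
class FlowResults:
    """Flow state of a network plus solver diagnostics.

    The per-vessel arrays (q, v_rbc, H_T, μ_LD, q_rbc) live on the network's
    vessels; this object carries node pressures and reconstruction metadata.
    """

    network: CapillaryNetwork
    node_pressures: dict[int, float]
    inflow_H_T: float
    converged: bool = True
    n_outer: int = 0
    history: list[float] = field(default_factory=list)
    misfit_rms: float = np.nan          # relative RMS error on measured vessels
    measured_ids: list[int] = field(default_factory=list)
    zero_flow_ids: list[int] = field(default_factory=list)

    def conservation(self) -> dict[str, float]:
        return conservation_residuals(self.network)

    def velocities(self) -> pd.Series:
        return pd.Series({vid: v.v_rbc for vid, v in self.network.vessels.items()})

    def summary(self) -> str:
        net = self.network
        v = np.array([abs(x.v_rbc) for x in net.vessels.values()])
        h = np.array([x.H_T for x in net.vessels.values()])
        cons = self.conservation()
        lines = [
            "Flow solution",
            "=" * 46,
            f"vessels                 {net.n_vessels:10d}",
            f"converging bifurcations {net.n_converging_bifurcations():10d}",
            f"|v_rbc| mean ± SD       {v.mean()/1e3:7.3f} ± {v.std()/1e3:.3f} mm/s",
            f"tube hematocrit         {np.nanmean(h):7.3f} ± {np.nanstd(h):.3f}",
            f"volume conservation     {cons['volume']:10.2e}",
            f"RBC-flux conservation   {cons['rbc_flux']:10.2e}",
            f"outer iterations        {self.n_outer:10d}",
        ]
        if self.measured_ids:
            lines.append(f"measurement misfit RMS  {self.misfit_rms:10.3%}")
        return "\n".join(lines)


# --------------------------------------------------------------------- direct


def _resistances(net: CapillaryNetwork, H: dict[int, float]) -> dict[int, float]:
    # geometry arrays cached on the network object (diameters and lengths
    # are fixed during a solve)
    cached = getattr(net, "_geom_cache", None)
    if cached is None or cached[0] != net.n_vessels:
        vids = list(net.vessels)
        d = np.array([net.vessels[v].diameter for v in vids])
        L = np.array([net.vessels[v].length for v in vids])
        cached = (net.n_vessels, vids, d, L)
        net._geom_cache = cached
    _, vids, d, L = cached
    h = np.array([H[v] for v in vids])
    R = vessel_resistance(d, L, h)
    return dict(zip(vids, R))


def _linear_solve(net: CapillaryNetwork, boundary_p: dict[int, float],
                  R: dict[int, float]) -> dict[int, float]:
    """Solve nodal conservation for interior pressures (Dirichlet boundaries)."""
    interior = [nid for nid in net.nodes if nid not in boundary_p]
    idx = {nid: i for i, nid in enumerate(interior)}
    n = len(interior)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    for vid, v in net.vessels.items():
        g = 1.0 / R[vid]
        for a, b in ((v.node_a, v.node_b), (v.node_b, v.node_a)):
            if a in idx:
                diag[idx[a]] += g
                if b in idx:
                    rows.append(idx[a]); cols.append(idx[b]); vals.append(-g)
                else:
                    rhs[idx[a]] += g * boundary_p[b]
    if n:
        A = sp.csr_matrix((np.r_[vals, diag],
                           (np.r_[rows, np.arange(n)], np.r_[cols, np.arange(n)])),
                          shape=(n, n))
        try:
            p_int = spla.spsolve(A.tocsc(), rhs)
        except Exception as exc:  # singular system
            raise NetworkValidationError(f"singular pressure system: {exc}") from exc
        if not np.all(np.isfinite(p_int)):
            bad = [interior[i] for i in np.where(~np.isfinite(p_int))[0]]
            raise NetworkValidationError(
                f"singular pressure system; isolated nodes {bad[:5]}")
    else:
        p_int = np.empty(0)
    pressures = dict(boundary_p)
    pressures.update({nid: float(p_int[i]) for nid, i in idx.items()})
    return pressures


def _apply_flows(net: CapillaryNetwork, pressures: dict[int, float],
                 R: dict[int, float]) -> None:
    for vid, v in net.vessels.items():
        v.q = (pressures[v.node_a] - pressures[v.node_b]) / R[vid]
        v.v_rbc = v.q / v.lumen_area


def distribute_hematocrit(net: CapillaryNetwork, inflow_H_T: float = 0.25,
                          zero_flow_rel: float = 1e-12) -> list[int]:
    """Propagate RBC flux through the directed flow graph.

    Vessels are visited in topological order. Diverging two-child nodes split
    the RBC flux with the empirical phase-separation law; other splits are
    proportional to blood flow; converging nodes mix conservatively. Sets
    H_T, μ_LD and q_rbc on every vessel and returns the ids of zero-flow
    vessels (flagged, excluded from propagation).
    """
    qmax = max((abs(v.q) for v in net.vessels.values()), default=0.0)
    zero_ids = [vid for vid, v in net.vessels.items()
                if not np.isfinite(v.q) or abs(v.q) <= zero_flow_rel * qmax]
    for vid in zero_ids:
        v = net.vessels[vid]
        v.q = 0.0
        v.H_T = 0.0
        v.mu_LD = 0.0
        v.q_rbc = 0.0
    dg = net.directed_graph()
    try:
        order = list(nx.topological_sort(dg))
    except nx.NetworkXUnfeasible as exc:
        raise NetworkValidationError("directed flow graph contains a cycle") from exc

    influx: dict[int, float] = {nid: 0.0 for nid in net.nodes}
    for nid in order:
        node = net.nodes[nid]
        children = [net.vessels[vid] for vid in node.vessel_ids
                    if vid not in zero_ids and net.vessels[vid].upstream_node() == nid]
        if not children:
            continue
        if node.is_boundary:
            # a boundary node feeding vessels is a functional inflow
            flux_in = sum(abs(c.q) for c in children) * inflow_H_T
            h_feed = inflow_H_T
            d_feed = float(np.mean([c.diameter for c in children]))
        else:
            flux_in = influx[nid]
            q_in = sum(abs(net.vessels[vid].q) for vid in node.vessel_ids
                       if vid not in zero_ids
                       and net.vessels[vid].downstream_node() == nid)
            h_feed = flux_in / q_in if q_in > 0 else 0.0
            parents = [net.vessels[vid] for vid in node.vessel_ids
                       if vid not in zero_ids
                       and net.vessels[vid].downstream_node() == nid]
            d_feed = (sum(p.diameter * abs(p.q) for p in parents) / q_in
                      if q_in > 0 else 0.0)
        q_children = np.array([abs(c.q) for c in children])
        if len(children) == 2 and node.boundary_kind == "interior":
            frac = phase_separation_fractions(
                q_children, [c.diameter for c in children], d_feed, h_feed)
        else:
            frac = q_children / q_children.sum()
        flux = flux_in * frac
        # cap child hematocrit, redistributing the excess conservatively
        cap = H_MAX * q_children
        for _ in range(len(children)):
            over = flux - cap
            excess = np.sum(over[over > 0])
            if excess <= 0:
                break
            flux = np.minimum(flux, cap)
            room = cap - flux
            if room.sum() <= excess:  # everything capped; keep conservation
                flux = flux + over.clip(min=0)
                break
            flux = flux + excess * (room / room.sum())
        for c, f in zip(children, flux):
            c.q_rbc = float(np.sign(c.q) * f)
            c.H_T = float(f / abs(c.q)) if c.q != 0 else 0.0
            c.mu_LD = min(min(c.H_T, 0.999) * (c.r_p / c.r_c) ** 2, 1.0)
            influx[c.downstream_node()] += f
    return zero_ids


def conservation_residuals(net: CapillaryNetwork) -> dict[str, float]:
    """Max relative nodal imbalance of volume flow and RBC flux."""
    res = {"volume": 0.0, "rbc_flux": 0.0}
    scale_q = np.mean([abs(v.q) for v in net.vessels.values()]) or 1.0
    scale_f = np.mean([abs(v.q_rbc) for v in net.vessels.values()
                       if np.isfinite(v.q_rbc)]) or 1.0
    for node in net.nodes.values():
        if node.is_boundary:
            continue
        dq = sum(net.vessels[vid].q * (1 if net.vessels[vid].node_b == node.id else -1)
                 for vid in node.vessel_ids)
        df = sum(net.vessels[vid].q_rbc * (1 if net.vessels[vid].node_b == node.id else -1)
                 for vid in node.vessel_ids if np.isfinite(net.vessels[vid].q_rbc))
        res["volume"] = max(res["volume"], abs(dq) / scale_q)
        res["rbc_flux"] = max(res["rbc_flux"], abs(df) / scale_f)
    return res


def solve_pressures(net: CapillaryNetwork, boundary_pressures: dict[int, float],
                    inflow_H_T: float = 0.25, max_outer: int = 300,
                    tol: float = 1e-6) -> FlowResults:
    """Solve the coupled pressure/hematocrit problem for given boundary pressures.

    Iterates linear pressure solves with hematocrit redistribution (which
    feeds back on resistance through the viscosity law) to a fixed point.
    """
    missing = [nid for nid in net.boundary_nodes() if nid not in boundary_pressures]
    if missing:
        raise ValueError(f"boundary nodes without pressure: {missing}")
    H = {vid: inflow_H_T for vid in net.vessels}
    q_old = None
    history: list[float] = []
    zero_ids: list[int] = []
    # damping against phase-separation limit cycles; tightened if the
    # iteration has not converged after the first phases
    for it in range(1, max_outer + 1):
        relax = 0.3 if it <= max_outer // 2 else \
            (0.12 if it <= 3 * max_outer // 4 else 0.05)
        R = _resistances(net, H)
        pressures = _linear_solve(net, boundary_pressures, R)
        _apply_flows(net, pressures, R)
        zero_ids = distribute_hematocrit(net, inflow_H_T)
        q = np.array([v.q for v in net.vessels.values()])
        if q_old is not None:
            change = np.max(np.abs(q - q_old)) / (np.max(np.abs(q)) or 1.0)
            history.append(float(change))
            if change < tol:
                return FlowResults(net, pressures, inflow_H_T, True, it, history,
                                   zero_flow_ids=zero_ids)
        H = {vid: (1 - relax) * H[vid] + relax * max(v.H_T, 0.0)
             for vid, v in net.vessels.items()}
        q_old = q
    raise FlowConvergenceError(
        f"hematocrit loop did not converge in {max_outer} iterations", history)


# ------------------------------------------------------------- reconstruction


class FlowReconstruction:
    """Reconstruct boundary pressures from sparse RBC velocity measurements.

    Minimizes J(p_B) = Σ_e q_e² R_e + λ Σ_m w_m (|v_m| − v̂_m)² over the
    boundary pressures p_B, subject to a mean pressure drop of at least
    ``dp_min`` between inflow and outflow boundaries (which prevents the
    trivial zero-flow minimum when measurements are absent). The absolute
    value is handled by iterating over velocity sign patterns, each step a
    linear least-squares solve; an outer loop redistributes hematocrit.

    Parameters
    ----------
    net : CapillaryNetwork
        Network with boundary nodes identified and radii derived.
    measurements : sequence of (vessel_id, v_rbc) or DataFrame
        Measured RBC speeds, μm/s (positive).
    inflow_H_T : float
        Tube hematocrit at inflow boundaries.
    lambda_factor : float
        Misfit weight relative to balancing both terms at initialization.
    dp_min : float
        Minimum admissible mean inflow–outflow pressure drop, mmHg.
    """

    def __init__(self, net: CapillaryNetwork, measurements, inflow_H_T: float = 0.25,
                 lambda_factor: float = 1e6, dp_min: float = 5.0,
                 weights=None, p_ref: float = 40.0, dp_init: float = 30.0):
        self.net = net
        if isinstance(measurements, pd.DataFrame):
            cols = ["vessel_id", "v_rbc"]
            if "noise_sd" in measurements.columns:
                cols.append("noise_sd")
            measurements = list(zip(*[measurements[c] for c in cols]))
        self.meas_ids = [int(m[0]) for m in measurements]
        self.meas_v = np.array([float(m[1]) for m in measurements])
        self.meas_noise = np.array([float(m[2]) if len(m) > 2 else 0.0
                                    for m in measurements])
        if len(self.meas_ids) == 0:
            self.meas_v = np.empty(0)
        if np.any(self.meas_v <= 0):
            raise ValueError("measured speeds must be positive")
        unknown = set(self.meas_ids) - set(net.vessels)
        if unknown:
            raise ValueError(f"measurements reference unknown vessels {sorted(unknown)}")
        # default: relative weighting (line-scan velocimetry errors scale with
        # speed), so slow vessels are fitted as tightly as fast ones; floored
        # at the noise scale so that measurements below their own noise level
        # cannot dominate the misfit
        if weights is None:
            floor = np.maximum(np.maximum(self.meas_v, self.meas_noise), 1e-6)
            self.weights = 1.0 / floor**2
        else:
            self.weights = np.asarray(weights, float)
        if self.meas_ids and not np.any(self.weights > 0):
            raise ValueError("all measurement weights are zero")
        self.inflow_H_T = inflow_H_T
        self.lambda_factor = lambda_factor
        self.dp_min = dp_min
        self.p_ref = p_ref
        self.dp_init = dp_init

    # -- linear algebra helpers
    def _response(self, R: dict[int, float]):
        """Map W with q = W p_B for the current resistances."""
        net = self.net
        bnodes = self.bnodes
        interior = [nid for nid in net.nodes if nid not in self.bset]
        idx = {nid: i for i, nid in enumerate(interior)}
        n = len(interior)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        B = np.zeros((n, len(bnodes)))
        bidx = {nid: j for j, nid in enumerate(bnodes)}
        for vid, v in net.vessels.items():
            g = 1.0 / R[vid]
            for a, b in ((v.node_a, v.node_b), (v.node_b, v.node_a)):
                if a in idx:
                    diag[idx[a]] += g
                    if b in idx:
                        rows.append(idx[a]); cols.append(idx[b]); vals.append(-g)
                    else:
                        B[idx[a], bidx[b]] += g
        if n:
            A = sp.csc_matrix((np.r_[vals, diag],
                               (np.r_[rows, np.arange(n)], np.r_[cols, np.arange(n)])),
                              shape=(n, n))
            Pint = spla.splu(A).solve(B)  # interior response to boundary pressures
        else:
            Pint = np.empty((0, len(bnodes)))
        # full pressure response rows per node
        def prow(nid):
            if nid in bidx:
                e = np.zeros(len(bnodes)); e[bidx[nid]] = 1.0
                return e
            return Pint[idx[nid]]
        W = np.zeros((net.n_vessels, len(bnodes)))
        Rvec = np.zeros(net.n_vessels)
        for k, (vid, v) in enumerate(net.vessels.items()):
            W[k] = (prow(v.node_a) - prow(v.node_b)) / R[vid]
            Rvec[k] = R[vid]
        return W, Rvec

    def _solve_quadratic(self, A: np.ndarray, b: np.ndarray):
        """Minimize pᵀAp − 2bᵀp over p_B with mean(p_B) = p_ref (gauge fix),
        enforcing the mean-drop inequality by an equality re-solve if violated."""
        nb = len(self.bnodes)
        ones = np.ones(nb) / np.sqrt(nb)
        Q, _ = np.linalg.qr(np.eye(nb) - np.outer(ones, ones))
        Bn = Q[:, :nb - 1]  # orthonormal basis orthogonal to 1
        p0 = np.full(nb, self.p_ref)
        Ar = Bn.T @ A @ Bn
        br = Bn.T @ (b - A @ p0)
        y = np.linalg.lstsq(Ar, br, rcond=None)[0]
        p = p0 + Bn @ y
        drop = self.cvec @ p
        if drop < self.dp_min - 1e-12:
            c = Bn.T @ self.cvec
            # KKT system for equality-constrained minimum
            K = np.block([[Ar, c[:, None]], [c[None, :], np.zeros((1, 1))]])
            rhs = np.r_[br, self.dp_min - self.cvec @ p0]
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
            p = p0 + Bn @ sol[:nb - 1]
        return p

    def _fit_signs(self, A_pow, Wv, lam, p_start, max_sign_iters):
        """Best-effort minimization over velocity sign patterns.

        Alternates the quadratic solve with sign updates to a fixed point,
        then refines with greedy single flips and pair flips among the
        worst-residual measurements (the |v| misfit is non-convex and the
        fixed points of the alternation are only local minima).
        """
        w = self.weights

        def solve_for(signs):
            A = A_pow + lam * Wv.T @ (Wv * w[:, None])
            b = lam * (Wv * w[:, None]).T @ (signs * self.meas_v)
            return self._solve_quadratic(A, b)

        def objective(p):
            return (float(p @ A_pow @ p)
                    + lam * float(np.sum(w * (np.abs(Wv @ p) - self.meas_v) ** 2)))

        signs = np.sign(Wv @ p_start)
        signs[signs == 0] = 1.0
        p = p_start
        for _ in range(max_sign_iters):
            p = solve_for(signs)
            new_signs = np.sign(Wv @ p)
            new_signs[new_signs == 0] = 1.0
            if np.array_equal(new_signs, signs):
                break
            signs = new_signs
        j_best = objective(p)
        for _ in range(10):
            improved = False
            for i in range(len(self.meas_v)):
                trial = signs.copy()
                trial[i] *= -1.0
                p_trial = solve_for(trial)
                j_trial = objective(p_trial)
                if j_trial < j_best * (1.0 - 1e-12):
                    signs, p, j_best = trial, p_trial, j_trial
                    improved = True
            if not improved:
                resid = w * (np.abs(Wv @ p) - self.meas_v) ** 2
                worst = np.argsort(-resid)[:10]
                for a in range(len(worst)):
                    for b_ in range(a + 1, len(worst)):
                        trial = signs.copy()
                        trial[worst[a]] *= -1.0
                        trial[worst[b_]] *= -1.0
                        p_trial = solve_for(trial)
                        j_trial = objective(p_trial)
                        if j_trial < j_best * (1.0 - 1e-12):
                            signs, p, j_best = trial, p_trial, j_trial
                            improved = True
            if not improved:
                # wrong directions typically form connected chains; flip the
                # connected components of the high-residual subgraph jointly
                rel = np.abs(np.abs(Wv @ p) - self.meas_v) / self.meas_v
                bad = np.where(rel > 0.05)[0]
                if len(bad):
                    sub = nx.Graph()
                    for i in bad:
                        a_, b_ = self._meas_nodes[i]
                        sub.add_edge(a_, b_, idx=int(i))
                    for comp in nx.connected_components(sub):
                        idxs = [d["idx"] for _, _, d in
                                sub.subgraph(comp).edges(data=True)]
                        trial = signs.copy()
                        trial[idxs] *= -1.0
                        p_trial = solve_for(trial)
                        j_trial = objective(p_trial)
                        if j_trial < j_best * (1.0 - 1e-12):
                            signs, p, j_best = trial, p_trial, j_trial
                            improved = True
            if not improved:
                break
        return p, signs, j_best

    def fit(self, max_outer: int = 120, tol: float = 1e-6,
            max_sign_iters: int = 60, n_starts: int = 60,
            n_candidates: int = 6, scout_outer: int = 40,
            scout_tol: float = 1e-4) -> FlowResults:
        """Reconstruct the flow field.

        Three phases: (A) a multistart search over velocity sign patterns
        under the uniform inflow hematocrit; (B) a short self-consistent
        hematocrit loop ("scout") for each of the best distinct candidates —
        needed because the apparent-viscosity feedback can make a sign
        pattern that wins under uniform hematocrit lose once hematocrit is
        redistributed; (C) a full-tolerance polish from the best scout.
        """
        self._prepare()
        if not self.meas_ids:
            # pure power minimization under the drop constraint. The
            # discontinuous phase-separation law sustains micro-cycles of
            # ~1e-4 relative flow amplitude in this mode, so the fixed point
            # is resolved to a correspondingly looser tolerance.
            return self._run_loop(self._p_init, max(max_outer, 600),
                                  max(tol, 1e-4), max_sign_iters)[1]
        # Phase A: candidate generation under uniform hematocrit
        H = {vid: self.inflow_H_T for vid in self.net.vessels}
        R = _resistances(self.net, H)
        W, Rvec = self._response(R)
        A_pow = W.T @ (W * Rvec[:, None])
        Wv = W[self._m_rows] / self._areas[self._m_rows][:, None]
        # calibrate the initial pressure drop to the measured speed scale, so
        # the power/misfit balance (and hence λ) reflects the true flow
        # magnitude rather than the arbitrary dp_init
        if len(self.meas_v):
            v0 = np.abs(Wv @ self._p_init)
            scale = float(np.mean(self.meas_v) / max(np.mean(v0), 1e-12))
            scale = float(np.clip(scale, 0.05, 50.0))
            self._p_init = self.p_ref + (self._p_init - self.p_ref) * scale
        lam = self._lambda(A_pow, Wv)
        rng = np.random.default_rng(97531)
        starts = [self._p_init] + [self._p_init + rng.normal(0, 0.7 * self.dp_init,
                                                             size=self._p_init.shape)
                                   for _ in range(n_starts)]
        cands: dict[tuple, tuple] = {}
        for p_start in starts:
            p, signs, j = self._fit_signs(A_pow, Wv, lam, p_start, max_sign_iters)
            key = tuple(signs.astype(int))
            if key not in cands or j < cands[key][2]:
                cands[key] = (p, signs, j)
        ranked = sorted(cands.values(), key=lambda t: t[2])
        if os.environ.get("COSHNET_DEBUG"):
            print(f"[debug] {len(ranked)} candidates")
        # Phase B: score every candidate by its self-consistent measurement
        # misfit, holding its sign pattern frozen through the hematocrit loop.
        # A quick pass over all candidates, then a long pass over the best few
        # (the coupled pressure/hematocrit iteration settles slowly).
        quick = []
        for p_cand, signs, _ in ranked:
            try:
                res = self._run_loop(p_cand, scout_outer, scout_tol,
                                     max_sign_iters, freeze_signs=signs,
                                     require_convergence=False)
            except NetworkValidationError:
                continue
            quick.append((res[1].misfit_rms, p_cand, signs))
            if res[1].misfit_rms < 1e-4:
                break
        if not quick:
            raise FlowConvergenceError("no sign candidate reached a "
                                       "self-consistent flow state")
        quick.sort(key=lambda t: t[0])
        if os.environ.get("COSHNET_DEBUG"):
            print("[debug] quick:", [round(q[0],5) for q in quick[:8]])
        best = None
        best_signs = None
        for _, p_cand, signs in quick[:n_candidates]:
            try:
                res = self._run_loop(p_cand, 300, scout_tol, max_sign_iters,
                                     freeze_signs=signs,
                                     require_convergence=False)
            except NetworkValidationError:
                continue
            if best is None or res[1].misfit_rms < best[1].misfit_rms:
                best = res
                best_signs = signs
            if best[1].misfit_rms < 1e-4:
                break
        if best is None:
            raise FlowConvergenceError("no sign candidate reached a "
                                       "self-consistent flow state")
        # Phase C: residual-guided single sign flips, each candidate flip
        # scored by a fresh self-consistent loop (the frozen-hematocrit
        # surrogate inside _fit_signs can rank patterns wrongly once the
        # viscosity feedback acts); best flip per round, while improving
        for _ in range(8):
            if best[1].misfit_rms < 1e-3:
                break
            # restore the incumbent's flow state (trials overwrite the network)
            self._run_loop(best[0], 300, scout_tol, max_sign_iters,
                           freeze_signs=best_signs, require_convergence=False)
            v_model = np.abs(np.array([self.net.vessels[v].v_rbc
                                       for v in self.meas_ids]))
            rel = np.abs(v_model - self.meas_v) / self.meas_v
            order = np.argsort(-rel)
            flip_sets = [[i] for i in order[:20]]
            flip_sets += [[order[a], order[b]]
                          for a in range(6) for b in range(a + 1, 6)]
            # slow vessels match their speed under either sign; their signs
            # are the weakly determined ones, so probe them explicitly
            slow = np.argsort(self.meas_v)[:8]
            flip_sets += [[i] for i in slow if i not in order[:20]]
            trials = []
            for idxs in flip_sets:
                trial = best_signs.copy()
                trial[idxs] *= -1.0
                try:
                    res_t = self._run_loop(best[0], 300, scout_tol,
                                           max_sign_iters, freeze_signs=trial,
                                           require_convergence=False)
                except NetworkValidationError:
                    continue
                trials.append((res_t[1].misfit_rms, res_t, trial))
            if not trials:
                break
            trials.sort(key=lambda t: t[0])
            if os.environ.get("COSHNET_DEBUG"):
                print(f"[debug] round: best flip {trials[0][0]:.5f} vs current {best[1].misfit_rms:.5f}")
            if trials[0][0] < 0.98 * best[1].misfit_rms:
                best = trials[0][1]
                best_signs = trials[0][2]
            else:
                break
        p_best = best[0]
        if os.environ.get("COSHNET_DEBUG"):
            print(f"[debug] phase C done: {best[1].misfit_rms:.6f}")
        # Phase D: full-tolerance polish. Try both the frozen best pattern and
        # free sign refinement (each can win, depending on whether the frozen
        # pattern is exactly right or one refinement step away); keep the
        # better fit and leave its state on the network.
        res_frozen = self._run_loop(p_best, max(max_outer, 400), tol,
                                    max_sign_iters, freeze_signs=best_signs,
                                    require_convergence=False)
        m_frozen = res_frozen[1].misfit_rms
        try:
            res_free = self._run_loop(p_best, max_outer, tol, max_sign_iters,
                                      require_convergence=False)
        except NetworkValidationError:
            res_free = None
        if res_free is not None and res_free[1].misfit_rms < m_frozen:
            return res_free[1]
        return self._run_loop(p_best, max(max_outer, 400), tol, max_sign_iters,
                              freeze_signs=best_signs,
                              require_convergence=False)[1]

    def _prepare(self) -> None:
        net = self.net
        self.bnodes = net.boundary_nodes()
        self.bset = set(self.bnodes)
        if not self.bnodes:
            raise NetworkValidationError("network has no boundary nodes")
        n_in = [nid for nid in self.bnodes if net.nodes[nid].boundary_kind == "inflow"]
        n_out = [nid for nid in self.bnodes if net.nodes[nid].boundary_kind == "outflow"]
        if not n_in or not n_out:
            raise NetworkValidationError("need both inflow and outflow boundary nodes")
        self.cvec = np.zeros(len(self.bnodes))
        for j, nid in enumerate(self.bnodes):
            self.cvec[j] = 1.0 / len(n_in) if nid in n_in else -1.0 / len(n_out)
        vid_row = {vid: k for k, vid in enumerate(net.vessels)}
        self._m_rows = np.array([vid_row[v] for v in self.meas_ids], dtype=int)
        self._meas_nodes = [(net.vessels[v].node_a, net.vessels[v].node_b)
                            for v in self.meas_ids]
        self._areas = np.array([v.lumen_area for v in net.vessels.values()])
        self._p_init = np.array([self.p_ref + (self.dp_init if nid in n_in else 0.0)
                                 for nid in self.bnodes])
        self._lam_cache = None

    def _lambda(self, A_pow, Wv) -> float:
        """Misfit weight, frozen at its first evaluation for consistency.

        With a known measurement noise level, λ follows the discrepancy
        principle: the misfit term at its noise floor balances the hydraulic
        power, so the power term keeps regularizing unmeasured vessels. For
        noise-free measurements λ is taken large enough that the misfit
        dominates (exact-recovery regime)."""
        if self._lam_cache is None:
            power0 = float(self._p_init @ A_pow @ self._p_init)
            noise_floor = float(np.sum(self.weights * self.meas_noise ** 2))
            if noise_floor > 0:
                self._lam_cache = power0 / noise_floor
            else:
                v0 = Wv @ self._p_init
                misfit0 = float(np.sum(self.weights
                                       * (np.abs(v0) - self.meas_v) ** 2))
                self._lam_cache = self.lambda_factor * power0 / max(misfit0, 1e-30)
        return self._lam_cache

    def _run_loop(self, p0: np.ndarray, max_outer: int, tol: float,
                  max_sign_iters: int, freeze_signs=None,
                  require_convergence: bool = True) -> tuple[np.ndarray, FlowResults]:
        """Outer hematocrit loop from boundary pressures ``p0``. With
        ``freeze_signs`` the velocity sign pattern is held fixed (candidate
        scouting); otherwise warm-started sign refinement runs each
        iteration."""
        net = self.net
        m_rows = self._m_rows
        H = {vid: self.inflow_H_T for vid in net.vessels}
        q_old = None
        history: list[float] = []
        p = p0
        for it in range(1, max_outer + 1):
            # graduated damping against phase-separation limit cycles
            relax = 0.3 if it <= max_outer // 2 else \
                (0.12 if it <= 3 * max_outer // 4 else 0.05)
            R = _resistances(net, H)
            W, Rvec = self._response(R)
            A_pow = W.T @ (W * Rvec[:, None])
            if len(m_rows) and freeze_signs is not None:
                Wv = W[m_rows] / self._areas[m_rows][:, None]
                lam = self._lambda(A_pow, Wv)
                w = self.weights
                A = A_pow + lam * Wv.T @ (Wv * w[:, None])
                b = lam * (Wv * w[:, None]).T @ (freeze_signs * self.meas_v)
                p = self._solve_quadratic(A, b)
            elif len(m_rows):
                Wv = W[m_rows] / self._areas[m_rows][:, None]
                lam = self._lambda(A_pow, Wv)
                p, _, _ = self._fit_signs(A_pow, Wv, lam, p, max_sign_iters)
            else:
                p = self._solve_quadratic(A_pow, np.zeros(len(self.bnodes)))
            pressures = {nid: float(p[j]) for j, nid in enumerate(self.bnodes)}
            full_p = _linear_solve(net, pressures, R)
            _apply_flows(net, full_p, R)
            zero_ids = distribute_hematocrit(net, self.inflow_H_T)
            q = np.array([v.q for v in net.vessels.values()])
            if q_old is not None:
                change = np.max(np.abs(q - q_old)) / (np.max(np.abs(q)) or 1.0)
                history.append(float(change))
                if change < tol:
                    break
            H = {vid: (1 - relax) * H[vid] + relax * max(v.H_T, 0.0)
                 for vid, v in net.vessels.items()}
            q_old = q
        else:
            if require_convergence:
                raise FlowConvergenceError(
                    f"flow reconstruction did not converge in {max_outer} "
                    "iterations", history)
        v_model = np.abs(np.array([net.vessels[vid].v_rbc for vid in self.meas_ids]))
        misfit_rms = (float(np.sqrt(np.mean(((v_model - self.meas_v) / self.meas_v) ** 2)))
                      if len(self.meas_ids) else np.nan)
        return p, FlowResults(net, full_p, self.inflow_H_T, True, it, history,
                              misfit_rms=misfit_rms,
                              measured_ids=list(self.meas_ids),
                              zero_flow_ids=zero_ids)
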