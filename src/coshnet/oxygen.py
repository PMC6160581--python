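"""Hemoglobin-saturation transport along capillaries and through networks.

The core model is an advection balance for the saturation S of hemoglobin in
flowing RBCs: the convective oxygen carrying capacity Q_O2(S) times dS/dx
equals minus the local tissue extraction rate j_t (per unit vessel length).
Q_O2 combines the RBC-bound capacity (μ_LD π r_c² C0) and the dissolved
capacity of the plasma at hemoglobin equilibrium (π r_p² α_eff dP_eq/dS),
both advected at the RBC velocity. Axial diffusion is neglected.

Saturation heterogeneity is carried as a discrete distribution of (S, w)
"atoms" per vessel cross-section. At a converging bifurcation the child's
inlet distribution is the RBC-flux-weighted union of the parents' distal
atoms; at a diverging bifurcation children inherit the parent distribution
unchanged, so the scheme contains no RBC diffusive interaction by
construction — that mechanism lives in the particle model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.integrate import solve_ivp

from .network import CapillaryNetwork, Vessel, NetworkValidationError
from .params import OxygenParameters, SolverSettings

__all__ = [
    "hill_peq",
    "hill_seq",
    "hill_dpeq_ds",
    "convective_capacity",
    "extraction_rate",
    "SaturationDistribution",
    "SaturationProfile",
    "integrate_vessel",
    "propagate_network",
    "NetworkSaturation",
    "oxygen_balance",
]

logger = logging.getLogger(__name__)


# ------------------------------------------------------------ Hill equilibrium


def hill_peq(S, P50: float = 47.9, hill_n: float = 2.64, s_clip: float = 1e-9):
    """Equilibrium oxygen tension P_eq(S) = P50 (S/(1−S))^(1/n), mmHg."""
    s = np.clip(np.asarray(S, dtype=float), s_clip, 1.0 - s_clip)
    return P50 * (s / (1.0 - s)) ** (1.0 / hill_n)


def hill_seq(P, P50: float = 47.9, hill_n: float = 2.64):
    """Equilibrium saturation S_eq(P) = Pⁿ/(Pⁿ + P50ⁿ)."""
    p = np.asarray(P, dtype=float)
    if np.any(p < 0):
        raise ValueError("oxygen tension must be non-negative")
    pn = p**hill_n
    return pn / (pn + P50**hill_n)


def hill_dpeq_ds(S, P50: float = 47.9, hill_n: float = 2.64, s_clip: float = 1e-9):
    """Closed-form slope dP_eq/dS = P50/n (S/(1−S))^(1/n) / (S(1−S))."""
    s = np.clip(np.asarray(S, dtype=float), s_clip, 1.0 - s_clip)
    return P50 / hill_n * (s / (1.0 - s)) ** (1.0 / hill_n) / (s * (1.0 - s))


# --------------------------------------------------------- capacity/extraction


def convective_capacity(S, vessel: Vessel, params: OxygenParameters):
    """Convective oxygen carrying capacity Q_O2(S), (μm³ O₂/s) per unit S.

    Q_O2 = v_rbc (μ_LD π r_c² C0 + π r_p² α_eff dP_eq/dS); the hemoglobin
    term dominates, the plasma term adds the dissolved oxygen advected at
    equilibrium with the RBCs.
    """
    dp = hill_dpeq_ds(S, params.P50, params.hill_n)
    return abs(vessel.v_rbc) * (vessel.mu_LD * np.pi * vessel.r_c**2 * params.C0
                                + np.pi * vessel.r_p**2 * params.alpha_eff * dp)


def extraction_rate(r_t: float, r_w: float, M0: float) -> float:
    """Tissue oxygen extraction per unit vessel length, j_t = M0 π (r_t²−r_w²)."""
    if r_t < r_w:
        raise ValueError(f"tissue radius {r_t} below wall radius {r_w}")
    return M0 * np.pi * (r_t**2 - r_w**2)


# ------------------------------------------------------------------ atom types


@dataclass
class SaturationDistribution:
    """Discrete distribution of saturation atoms (S, w) with Σw = 1."""

    S: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.atleast_1d(np.asarray(self.S, dtype=float))
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if self.S.shape != self.w.shape:
            raise ValueError("S and w must have the same shape")
        if np.any(self.S < -1e-12) or np.any(self.S > 1 + 1e-12):
            raise ValueError("saturations must lie in [0, 1]")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {self.w.sum()}, not 1")

    @classmethod
    def delta(cls, S: float) -> "SaturationDistribution":
        return cls(np.array([S]), np.array([1.0]))

    @property
    def mean(self) -> float:
        return float(np.sum(self.S * self.w))

    @property
    def std(self) -> float:
        m = self.mean
        return float(np.sqrt(np.sum(self.w * (self.S - m) ** 2)))

    def merged(self, cap: int) -> "SaturationDistribution":
        """Merge the two closest-S atoms (mass-conserving weighted mean)
        until at most ``cap`` atoms remain."""
        S, w = self.S.copy(), self.w.copy()
        while len(S) > cap:
            order = np.argsort(S)
            S, w = S[order], w[order]
            gaps = np.diff(S)
            i = int(np.argmin(gaps))
            wm = w[i] + w[i + 1]
            sm = ((S[i] * w[i] + S[i + 1] * w[i + 1]) / wm if wm > 0
                  else 0.5 * (S[i] + S[i + 1]))
            S = np.r_[S[:i], sm, S[i + 2:]]
            w = np.r_[w[:i], wm, w[i + 2:]]
        return SaturationDistribution(S, w)


@dataclass
class SaturationProfile:
    """Per-vessel saturation solution: atoms S_k(x) on the arc coordinate."""

    vessel_id: int
    x: np.ndarray                    # (m,) arc positions, μm
    S_atoms: np.ndarray              # (k, m) per-atom saturation
    w: np.ndarray                    # (k,) atom weights
    floored: np.ndarray              # (k,) bool: atom hit S = 0

    @property
    def mean(self) -> np.ndarray:
        return self.w @ self.S_atoms

    @property
    def std(self) -> np.ndarray:
        m = self.mean
        return np.sqrt(np.clip(self.w @ (self.S_atoms - m) ** 2, 0.0, None))

    def inlet(self) -> SaturationDistribution:
        return SaturationDistribution(self.S_atoms[:, 0], self.w)

    def outlet(self) -> SaturationDistribution:
        return SaturationDistribution(self.S_atoms[:, -1], self.w)


# ------------------------------------------------------------- vessel solve


def integrate_vessel(S_in: SaturationDistribution, vessel: Vessel, j_t,
                     params: OxygenParameters,
                     settings: SolverSettings | None = None) -> SaturationProfile:
    """Integrate dS/dx = −j_t/Q_O2(S) for every atom along one vessel.

    ``j_t`` is a constant or a callable of arc position (≥ 0). Atoms are
    independent; each is floored at S = 0 (a fully desaturated RBC stops
    releasing oxygen). Adaptive Runge–Kutta with dense output.
    """
    settings = settings or SolverSettings()
    L = vessel.length
    jt_fun = j_t if callable(j_t) else (lambda x, c=float(j_t): c)
    if jt_fun(0.0) < 0 or jt_fun(L) < 0:
        raise ValueError("extraction rate must be non-negative")
    S0 = np.asarray(S_in.S, dtype=float)

    def rhs(x, S):
        dS = -jt_fun(x) / convective_capacity(np.clip(S, 0.0, 1.0),
                                              vessel, params)
        return np.where(S <= 0.0, 0.0, dS)  # floored atoms stop extracting

    sol = solve_ivp(rhs, (0.0, L), S0, method="RK45",
                    rtol=settings.ode_rtol, atol=settings.ode_atol,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE solve failed on vessel {vessel.id}: {sol.message}")
    x = np.linspace(0.0, L, settings.profile_points)
    S = np.clip(sol.sol(x), 0.0, 1.0)
    S = np.minimum.accumulate(S, axis=1)  # enforce monotone flooring exactly
    floored = S[:, -1] <= 0.0
    return SaturationProfile(vessel.id, x, S, S_in.w.copy(), floored)


# ------------------------------------------------------------- network solve


@dataclass
class NetworkSaturation:
    """Result of propagating saturation through a network."""

    profiles: dict[int, SaturationProfile]
    inlet: dict[int, SaturationDistribution]
    outlet: dict[int, SaturationDistribution]
    outflow_S: np.ndarray            # pooled distal atoms over outflow vessels
    outflow_w: np.ndarray            # RBC-flux × atom weights, Σ = 1
    skipped: list[int] = field(default_factory=list)

    @property
    def cosh(self) -> float:
        """Flow-weighted SD of outflow saturation."""
        m = np.sum(self.outflow_S * self.outflow_w)
        return float(np.sqrt(np.sum(self.outflow_w * (self.outflow_S - m) ** 2)))

    @property
    def mean_outflow(self) -> float:
        return float(np.sum(self.outflow_S * self.outflow_w))

    def vessel_means(self) -> dict[int, tuple[float, float]]:
        """(S̄_a, S̄_v) per vessel."""
        return {vid: (p.mean[0], p.mean[-1]) for vid, p in self.profiles.items()}


def propagate_network(net: CapillaryNetwork, inflow_S: dict[int, float],
                      radii: dict[int, float], params: OxygenParameters,
                      settings: SolverSettings | None = None) -> NetworkSaturation:
    """Propagate saturation distributions through a flow-directed network.

    Parameters
    ----------
    net : CapillaryNetwork
        With solved flow (q, v_rbc, μ_LD, q_rbc set).
    inflow_S : dict vessel id → S_a
        Inlet saturation for every inflow vessel.
    radii : dict vessel id → r_t
        Tissue radius per vessel (geometric or functional); sets the local
        extraction rate j_t = M0 π (r_t² − r_w²).
    """
    settings = settings or SolverSettings()
    dg = net.directed_graph()
    try:
        node_order = list(nx.topological_sort(dg))
    except nx.NetworkXUnfeasible as exc:
        raise NetworkValidationError("flow graph contains a cycle") from exc

    skipped = [vid for vid, v in net.vessels.items() if v.q == 0.0 or
               not np.isfinite(v.q)]
    if skipped:
        logger.info("propagate_network: skipping %d zero-flow vessels", len(skipped))

    profiles: dict[int, SaturationProfile] = {}
    inlet: dict[int, SaturationDistribution] = {}
    outlet: dict[int, SaturationDistribution] = {}

    for nid in node_order:
        node = net.nodes[nid]
        children = [net.vessels[vid] for vid in node.vessel_ids
                    if vid not in skipped
                    and net.vessels[vid].upstream_node() == nid]
        if not children:
            continue
        if node.is_boundary:  # functional inflow: blood enters here
            dists = {c.id: SaturationDistribution.delta(inflow_S[c.id])
                     for c in children}
        else:
            parents = [net.vessels[vid] for vid in node.vessel_ids
                       if vid not in skipped
                       and net.vessels[vid].downstream_node() == nid]
            total = sum(abs(p.q_rbc) for p in parents)
            if total <= 0:
                # no RBC flux reaches this node; children carry S = 0 stream
                dists = {c.id: SaturationDistribution.delta(0.0) for c in children}
            else:
                S = np.concatenate([outlet[p.id].S for p in parents])
                w = np.concatenate([outlet[p.id].w * (abs(p.q_rbc) / total)
                                    for p in parents])
                keep = w > 0
                if np.any(keep):
                    S, w = S[keep], w[keep]
                node_dist = SaturationDistribution(S, w / w.sum())
                node_dist = node_dist.merged(settings.atom_cap)
                dists = {c.id: node_dist for c in children}
        for c in children:
            d = dists[c.id]
            jt = extraction_rate(max(radii[c.id], c.r_w), c.r_w, params.M0)
            prof = integrate_vessel(d, c, jt, params, settings)
            profiles[c.id] = prof
            inlet[c.id] = d
            outlet[c.id] = prof.outlet()

    # pooled outflow distribution over sink vessels (no active children:
    # boundary outflows, plus vessels whose downstream subtree is excluded),
    # RBC-flux weighted
    out_ids = []
    for vid, v in net.vessels.items():
        if vid in skipped or vid not in outlet or abs(v.q_rbc) <= 0:
            continue
        node = net.nodes[v.downstream_node()]
        kids = [k for k in node.vessel_ids
                if k != vid and k not in skipped
                and np.isfinite(net.vessels[k].q) and net.vessels[k].q != 0.0
                and net.vessels[k].upstream_node() == node.id]
        if not kids:
            out_ids.append(vid)
    total = sum(abs(net.vessels[vid].q_rbc) for vid in out_ids)
    S_all, w_all = [], []
    for vid in out_ids:
        d = outlet[vid]
        S_all.append(d.S)
        w_all.append(d.w * abs(net.vessels[vid].q_rbc) / total)
    outflow_S = np.concatenate(S_all) if S_all else np.empty(0)
    outflow_w = np.concatenate(w_all) if w_all else np.empty(0)
    if len(outflow_w):
        outflow_w = outflow_w / outflow_w.sum()
    return NetworkSaturation(profiles, inlet, outlet, outflow_S, outflow_w,
                             skipped)


def oxygen_balance(net: CapillaryNetwork, result: NetworkSaturation,
                   radii: dict[int, float], params: OxygenParameters) -> dict:
    """Compare oxygen released by blood with tissue consumption.

    Released per vessel: q_rbc C0 ΔS̄ plus the plasma-equilibrium term;
    consumed per vessel: j_t L. Vessels with floored atoms are reported
    separately (they under-deliver by construction).
    """
    released = consumed = 0.0
    floored_ids = []
    for vid, prof in result.profiles.items():
        v = net.vessels[vid]
        if np.any(prof.floored):
            floored_ids.append(vid)
        dS = prof.S_atoms[:, 0] - prof.S_atoms[:, -1]
        dPeq = (hill_peq(prof.S_atoms[:, 0], params.P50, params.hill_n)
                - hill_peq(prof.S_atoms[:, -1], params.P50, params.hill_n))
        q_plasma = abs(v.v_rbc) * np.pi * v.r_p**2
        released += float(np.sum(prof.w * (abs(v.q_rbc) * params.C0 * dS
                                           + q_plasma * params.alpha_eff * dPeq)))
        jt = extraction_rate(max(radii[vid], v.r_w), v.r_w, params.M0)
        consumed += jt * v.length
    rel = abs(released - consumed) / consumed if consumed else np.nan
    return {"released": released, "consumed": consumed,
            "relative_error": rel, "floored_vessels": floored_ids}
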