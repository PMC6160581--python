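"""Synthetic capillary networks with cortical-capillary statistics.

Generates connected 3-D networks from a jittered cubic lattice with greedy
edge pruning (which drives junction degrees toward 3, the dominant degree of
cortical capillary meshes), moment-matched truncated-normal diameters, and
tortuous polyline centerlines whose arc lengths reproduce a target length
distribution. Also emulates sparse line-scan velocity measurements and
inflow saturation assignments, so that every downstream stage can be tested
without imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import optimize
from scipy.stats import truncnorm

from .network import CapillaryNetwork, NetworkNode, Vessel
from .flow import FlowResults, solve_pressures

__all__ = [
    "NetworkStatsTarget",
    "GenerationError",
    "generate_network",
    "assign_reference_flow",
    "sample_measurements",
    "assign_inflow_saturation",
]

MIN_LENGTH = 10.0        # μm, lower truncation of the vessel-length distribution
MAX_TORTUOSITY = 3.0     # cap on arc length / chord length


class GenerationError(RuntimeError):
    pass


@dataclass
class NetworkStatsTarget:
    """Target statistics for the generator (defaults: ~90-vessel cortical CN)."""

    n_vessels: int = 92
    diameter_mean: float = 5.03
    diameter_sd: float = 1.45
    diameter_floor: float = 3.0
    length_mean: float = 57.3
    length_sd: float = 41.1
    bounding_box: tuple[float, float, float] = (219.0, 220.0, 168.0)
    n_converging: int = 22
    v_rbc_mean: float = 879.0       # μm/s
    v_rbc_sd: float = 475.0         # μm/s
    inflow_H_T: float = 0.25

    @classmethod
    def mouse_cortex_1(cls) -> "NetworkStatsTarget":
        return cls()

    @classmethod
    def mouse_cortex_1_sub(cls) -> "NetworkStatsTarget":
        return cls(n_vessels=60, diameter_mean=4.91, diameter_sd=1.11,
                   length_mean=58.1, length_sd=39.9,
                   bounding_box=(126.0, 216.0, 152.0), n_converging=14,
                   v_rbc_mean=899.0, v_rbc_sd=518.0)

    @classmethod
    def mouse_cortex_2(cls) -> "NetworkStatsTarget":
        return cls(n_vessels=89, diameter_mean=5.01, diameter_sd=1.47,
                   length_mean=47.0, length_sd=34.5,
                   bounding_box=(194.0, 193.0, 149.0), n_converging=23,
                   v_rbc_mean=997.0, v_rbc_sd=564.0)

    @classmethod
    def mouse_cortex_2_sub(cls) -> "NetworkStatsTarget":
        return cls(n_vessels=45, diameter_mean=5.26, diameter_sd=1.59,
                   length_mean=52.5, length_sd=37.9,
                   bounding_box=(108.0, 148.0, 116.0), n_converging=14,
                   v_rbc_mean=1095.0, v_rbc_sd=592.0)

    def __post_init__(self) -> None:
        if self.n_vessels < 3:
            raise ValueError("n_vessels must be ≥ 3")
        box = np.asarray(self.bounding_box, float)
        if np.any(box <= 0):
            raise ValueError("bounding box extents must be positive")
        for name in ("diameter_mean", "diameter_sd", "length_mean", "length_sd",
                     "v_rbc_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ------------------------------------------------------------- distributions


def _truncnorm_params(mean: float, sd: float, lo: float) -> tuple[float, float]:
    """Parent (μ, σ) of a lower-truncated normal with given post-truncation moments."""

    def moments(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a = (lo - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, [mean, np.log(sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _sample_truncnorm(rng, n, mean, sd, lo):
    mu, sigma = _truncnorm_params(mean, sd, lo)
    a = (lo - mu) / sigma
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


# ----------------------------------------------------------------- centerline


def _tortuous_polyline(p0: np.ndarray, p1: np.ndarray, target_length: float,
                       rng: np.random.Generator, n_seg: int = 8) -> np.ndarray:
    """Polyline from p0 to p1 with arc length equal to ``target_length``.

    A smooth transverse bump (first + second harmonic, random orientation) is
    superposed on the chord; its amplitude is found by bisection. The arc
    length is matched to 1e-10 relative tolerance.
    """
    chord = p1 - p0
    c = np.linalg.norm(chord)
    t = np.linspace(0.0, 1.0, n_seg + 1)
    base = p0 + np.outer(t, chord)
    if target_length <= c * (1 + 1e-12):
        return base
    # orthonormal transverse basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(chord @ ref) > 0.9 * c:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(chord / c, ref); u /= np.linalg.norm(u)
    w = np.cross(chord / c, u)
    phi = rng.uniform(0, 2 * np.pi)
    psi = rng.uniform(0, 2 * np.pi)
    shape = (np.outer(np.sin(np.pi * t), np.cos(phi) * u + np.sin(phi) * w)
             + 0.35 * np.outer(np.sin(2 * np.pi * t), np.cos(psi) * u + np.sin(psi) * w))

    def arc(a):
        pts = base + a * shape
        return np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))

    lo, hi = 0.0, c
    while arc(hi) < target_length:
        hi *= 2.0
        if hi > 100 * c:
            raise GenerationError("cannot reach target arc length")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if arc(mid) < target_length:
            lo = mid
        else:
            hi = mid
        if (hi - lo) < 1e-12 * c:
            break
    return base + 0.5 * (lo + hi) * shape


# ------------------------------------------------------------------- topology


def _lattice_dims(box: np.ndarray, n_nodes: int, n_max: int) -> tuple[int, int, int]:
    """Integer lattice dimensions ≈ n_nodes (≤ n_max) with the box's aspect."""
    scale = (n_nodes / np.prod(box)) ** (1.0 / 3.0)
    dims = np.maximum(2, np.round(box * scale).astype(int))
    while np.prod(dims) > n_max and np.any(dims > 2):
        dims[np.argmax(dims / box)] -= 1
    grown = True
    while grown and np.prod(dims) < n_nodes:
        grown = False
        for axis in np.argsort(-box / dims):
            trial = dims.copy()
            trial[axis] += 1
            if np.prod(trial) <= n_max:
                dims = trial
                grown = True
                break
    return tuple(int(d) for d in dims)


def _build_topology(stats: NetworkStatsTarget, rng: np.random.Generator):
    """Jittered lattice + greedy pruning; returns (positions, edge list)."""
    box = np.asarray(stats.bounding_box, float)
    n = stats.n_vessels
    if n <= 6:
        # degenerate star: one interior node, n leaves (tiny test networks)
        center = box / 2.0
        golden = np.pi * (3.0 - np.sqrt(5.0))
        pos = [center]
        for i in range(n):
            zdir = 1.0 - 2.0 * (i + 0.5) / n
            r = np.sqrt(1.0 - zdir**2)
            d = np.array([r * np.cos(golden * i), r * np.sin(golden * i), zdir])
            pos.append(center + 0.4 * box * d)
        edges = [(0, i + 1) for i in range(n)]
        return np.array(pos), edges

    # junctions: uniform random points; candidate vessels: Delaunay edges
    # (natural broad distribution of junction spacings, with the short
    # chords the vessel-length distribution requires)
    from scipy.spatial import Delaunay
    n_nodes = max(8, int(round(0.87 * n)))
    positions = rng.uniform(1.0, box - 1.0, size=(n_nodes, 3))
    tri = Delaunay(positions)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for simplex in tri.simplices:
        for a in range(4):
            for b in range(a + 1, 4):
                g.add_edge(int(simplex[a]), int(simplex[b]))
    if g.number_of_edges() < n + 4:
        raise GenerationError(
            f"triangulation too small: {g.number_of_edges()} edges < {n}")

    def safe_remove(a, b) -> bool:
        g.remove_edge(a, b)
        if nx.is_connected(g):
            return True
        g.add_edge(a, b)
        return False

    def edge_len(a, b):
        return float(np.linalg.norm(positions[a] - positions[b]))

    med_len = np.median([edge_len(a, b) for a, b in g.edges()])

    # greedy pruning toward n vessels: drop long edges and high-degree
    # junctions first (capillary meshes connect near neighbours and are
    # dominated by degree-3 nodes), keeping the graph connected
    def prune_step() -> bool:
        edges = list(g.edges())
        scores = np.array([g.degree(a) + g.degree(b)
                           + 3.0 * edge_len(a, b) / med_len
                           for a, b in edges])
        scores += rng.uniform(0, 0.25, len(scores))
        return any(safe_remove(*edges[ei]) for ei in np.argsort(-scores))

    # reduce the mesh, but keep enough spare edges to carve boundary stubs
    min_boundary = 2 if n <= 20 else 4
    n_boundary = max(min_boundary, int(round(0.24 * n)))
    phase1 = n + int(2.5 * n_boundary)
    while g.number_of_edges() > phase1:
        if not prune_step():
            break
    order = np.array(sorted(g.nodes(), key=lambda i: positions[i][2]))
    candidates = []
    lo, hi = 0, len(order) - 1
    while lo <= hi:  # alternate extremes so both faces get boundary nodes
        candidates.append(order[hi]); hi -= 1
        if lo <= hi:
            candidates.append(order[lo]); lo += 1
    made = 0
    for node in candidates:
        if made >= n_boundary or g.number_of_edges() <= n:
            break
        while g.degree(node) > 1 and g.number_of_edges() > n:
            nbrs = sorted(g.neighbors(node),
                          key=lambda nb: (g.degree(nb), edge_len(node, nb)),
                          reverse=True)
            if not any(safe_remove(node, nb) for nb in nbrs):
                break
        if g.degree(node) == 1:
            made += 1

    while g.number_of_edges() > n:
        if not prune_step():
            raise GenerationError("pruning stalled: all remaining edges are bridges")
    return positions, list(g.edges())


def generate_network(stats: NetworkStatsTarget | None = None,
                     seed: int | np.random.Generator = 0,
                     max_retries: int = 10) -> CapillaryNetwork:
    """Generate a connected capillary network matching ``stats``.

    Degree-1 nodes become boundary nodes, labelled inflow in the upper half
    of the box (cortical-surface side) and outflow below. Diameters are drawn
    from a moment-matched truncated normal; vessel arc lengths reproduce the
    target length distribution by rank-matching tortuosity targets to lattice
    chords (with an affine moment correction after chord clamping).
    Seed-reproducible.
    """
    stats = stats or NetworkStatsTarget()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    last_err = None
    for _ in range(max_retries):
        try:
            return _generate_once(stats, rng)
        except GenerationError as err:
            last_err = err
    raise GenerationError(f"generation failed after {max_retries} retries: {last_err}")


def _generate_once(stats: NetworkStatsTarget, rng: np.random.Generator) -> CapillaryNetwork:
    positions, edges = _build_topology(stats, rng)
    deg = np.zeros(len(positions), int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    used = np.where(deg > 0)[0]
    leaves = [int(i) for i in used if deg[i] == 1]
    min_leaves = 2 if stats.n_vessels <= 20 else 4
    if len(leaves) < min_leaves and stats.n_vessels > 6:
        raise GenerationError(f"only {len(leaves)} boundary nodes after pruning")
    # boundary labelling: upper half of the box feeds, lower half drains
    z = positions[:, 2]
    leaf_order = sorted(leaves, key=lambda i: -z[i])
    if stats.n_vessels <= 6:
        n_in = max(1, len(leaves) // 2 + 1)
    else:
        n_in = max(2, len(leaves) // 2)
    inflow = set(leaf_order[:n_in])

    # vessel lengths: rank-match targets to chords, then moment-correct
    chords = np.array([np.linalg.norm(positions[a] - positions[b]) for a, b in edges])
    targets = np.sort(_sample_truncnorm(rng, len(edges), stats.length_mean,
                                        stats.length_sd, MIN_LENGTH))
    order = np.argsort(chords)
    lengths = np.empty(len(edges))
    lengths[order] = targets
    lengths = np.maximum(lengths, chords)
    # chord clamping biases the moments; find the affine map of the targets
    # whose clipped moments match the target mean/SD (nested bisection: the
    # clipped mean is monotone in the offset, the clipped SD in the scale)
    lo = np.maximum(chords, MIN_LENGTH)
    hi = MAX_TORTUOSITY * np.maximum(chords, MIN_LENGTH)
    t_centered = targets[np.argsort(np.argsort(lengths))] - targets.mean()

    def offset_for_mean(b):
        a_lo, a_hi = lo.min() - 5 * stats.length_sd, hi.max()
        for _ in range(80):
            a = 0.5 * (a_lo + a_hi)
            if np.clip(a + b * t_centered, lo, hi).mean() < stats.length_mean:
                a_lo = a
            else:
                a_hi = a
        return 0.5 * (a_lo + a_hi)

    def sd_at(b):
        return np.clip(offset_for_mean(b) + b * t_centered, lo, hi).std()

    b_lo, b_hi = 0.0, 1.0
    while sd_at(b_hi) < stats.length_sd and b_hi < 16:
        b_hi *= 2.0
    for _ in range(60):
        b = 0.5 * (b_lo + b_hi)
        if sd_at(b) < stats.length_sd:
            b_lo = b
        else:
            b_hi = b
    b = 0.5 * (b_lo + b_hi)
    lengths = np.clip(offset_for_mean(b) + b * t_centered, lo, hi)

    diameters = _sample_truncnorm(rng, len(edges), stats.diameter_mean,
                                  stats.diameter_sd, stats.diameter_floor)

    node_map = {int(i): k for k, i in enumerate(used)}
    nodes = {}
    for i in used:
        kind = "interior"
        if deg[i] == 1:
            kind = "inflow" if int(i) in inflow else "outflow"
        nodes[node_map[int(i)]] = NetworkNode(node_map[int(i)], positions[i],
                                              boundary_kind=kind)
    vessels = {}
    for vid, ((a, b), L, d) in enumerate(zip(edges, lengths, diameters)):
        cl = _tortuous_polyline(positions[a], positions[b], L, rng)
        vessels[vid] = Vessel(vid, node_map[a], node_map[b], cl, float(d))
    box = np.asarray(stats.bounding_box, float)
    net = CapillaryNetwork(vessels, nodes, np.array([[0.0, 0.0, 0.0], box]))
    net.derive_radii()
    net.validate()
    return net


# ----------------------------------------------------------------- flow truth


def assign_reference_flow(net: CapillaryNetwork, stats: NetworkStatsTarget | None = None,
                          seed: int | np.random.Generator = 0,
                          pressure_noise: float = 0.25,
                          n_calibration: int = 4) -> FlowResults:
    """Assign ground-truth flow by random heterogeneous boundary pressures.

    Inflow nodes receive ``Δp(1 + noise)``, outflow nodes ``noise``-perturbed
    zero (plus a common offset); Δp is calibrated so the realized mean RBC
    speed matches the target. This is the generator's reference ("true") flow
    used to emulate measurements.
    """
    stats = stats or NetworkStatsTarget()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    inflow = net.boundary_nodes("inflow")
    outflow = net.boundary_nodes("outflow")
    if not inflow or not outflow:
        raise GenerationError("network lacks inflow or outflow boundary nodes")
    base = 10.0

    def calibrated(noise):
        dp = 10.0
        result = None
        for _ in range(n_calibration):
            bp = {nid: base + dp * (1.0 + noise[nid]) for nid in inflow}
            bp.update({nid: base + dp * noise[nid] for nid in outflow})
            result = solve_pressures(net, bp, inflow_H_T=stats.inflow_H_T)
            v_mean = np.mean([abs(v.v_rbc) for v in net.vessels.values()])
            if v_mean <= 0:
                raise GenerationError("degenerate reference flow (zero mean velocity)")
            dp *= stats.v_rbc_mean / v_mean
        return result

    # perfusion screen: imaged cortical capillary networks are fully
    # perfused, so among a few boundary-pressure draws keep the one with the
    # fewest near-stagnant vessels
    from .flow import FlowConvergenceError, FlowReconstruction
    best = None
    last_err = None
    for _ in range(5):
        noise = {nid: rng.uniform(-pressure_noise, pressure_noise)
                 for nid in inflow + outflow}
        try:
            result = calibrated(noise)
        except FlowConvergenceError as err:  # skip pathological draws
            last_err = err
            continue
        v = np.array([abs(x.v_rbc) for x in net.vessels.values()])
        stagnant = float(np.mean(v < 0.05 * stats.v_rbc_mean))
        if best is None or stagnant < best[0]:
            best = (stagnant, noise)
        if stagnant == 0.0:
            break
    if best is None:
        raise GenerationError(f"no boundary-pressure draw converged: {last_err}")
    result = calibrated(best[1])

    # shape the speed distribution toward the target moments: draw target
    # speeds from a moment-matched truncated normal, rank-match them to the
    # provisional speeds, and find boundary pressures realizing them as
    # closely as the network structure admits (fully perfused, measured-like
    # velocity statistics)
    vids = list(net.vessels)
    v_now = np.array([abs(net.vessels[i].v_rbc) for i in vids])
    targets = np.sort(_sample_truncnorm(rng, len(vids), stats.v_rbc_mean,
                                        stats.v_rbc_sd, 0.12 * stats.v_rbc_mean))
    ranks = np.argsort(np.argsort(v_now))
    measurements = [(vid, float(targets[ranks[k]])) for k, vid in enumerate(vids)]
    try:
        shaped = FlowReconstruction(net, measurements,
                                    inflow_H_T=stats.inflow_H_T).fit()
        v_mean = np.mean([abs(x.v_rbc) for x in net.vessels.values()])
        if abs(v_mean - stats.v_rbc_mean) <= 0.5 * stats.v_rbc_mean:
            return shaped
    except FlowConvergenceError:
        pass
    # shaping failed for this realization; keep the calibrated random draw
    return calibrated(best[1])


# --------------------------------------------------------------- measurements


def sample_measurements(net: CapillaryNetwork, fraction: float = 0.4,
                        noise_sd: float = 50.0,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Emulate sparse line-scan RBC velocity measurements.

    Draws a random vessel subset of the given fraction and perturbs the true
    speeds with Gaussian noise of SD ``noise_sd`` (μm/s). Requires solved
    flow. Returns a DataFrame with columns vessel_id, v_rbc, noise_sd.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = int(round(fraction * net.n_vessels))
    if n < 1:
        raise ValueError("fraction too small: no vessels would be measured")
    # line scans require observable RBC motion: only vessels moving at
    # least ~1 μm/s are measurable
    flowing = [vid for vid in net.vessel_ids()
               if np.isfinite(net.vessels[vid].v_rbc)
               and abs(net.vessels[vid].v_rbc) >= 1.0]
    n = min(n, len(flowing))
    ids = rng.choice(flowing, size=n, replace=False)
    rows = []
    for vid in sorted(int(i) for i in ids):
        v = net.vessels[vid]
        if not np.isfinite(v.v_rbc):
            raise ValueError("flow must be solved before sampling measurements")
        meas = abs(v.v_rbc) + rng.normal(0.0, noise_sd)
        rows.append({"vessel_id": vid, "v_rbc": max(meas, 1.0),
                     "noise_sd": noise_sd})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- inflow S


def assign_inflow_saturation(net: CapillaryNetwork, mode: str = "constant",
                             value_or_range=0.6,
                             seed: int | np.random.Generator = 0) -> dict[int, float]:
    """Assign hemoglobin saturation to each inflow vessel.

    mode="constant": every inflow vessel gets the given value (default 0.6).
    mode="uniform": i.i.d. draws from [lo, hi] per inflow vessel
    (default range (0.5, 0.7)).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vessels = net.inflow_vessels()
    if not vessels:
        raise ValueError("no inflow vessels identified")
    if mode == "constant":
        s = float(value_or_range)
        if not 0.0 <= s <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")
        return {vid: s for vid in vessels}
    if mode == "uniform":
        if np.isscalar(value_or_range):
            lo, hi = 0.5, 0.7
        else:
            lo, hi = map(float, value_or_range)
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("saturation range must lie in [0, 1]")
        return {vid: float(rng.uniform(lo, hi)) for vid in vessels}
    raise ValueError(f"unknown mode {mode!r}")
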