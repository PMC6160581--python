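"""Path statistics, COSH/CTH metrics, model comparison and correlations.

COSH (capillary outflow saturation heterogeneity) is the RBC-flow-weighted
standard deviation of hemoglobin saturation at the distal ends of capillary
paths; CTH (capillary transit-time heterogeneity) is the weighted SD of RBC
transit times. This module extracts inflow→outflow paths from a
flow-directed network, computes weighted heterogeneity summaries, compares
the three transport models (saturation ODE with geometric radii — no
diffusive interaction; with functional radii — capillary interaction only;
particle surrogate — full interaction), and evaluates the correlation suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .network import CapillaryNetwork, NetworkValidationError
from .params import OxygenParameters, SolverSettings
from .oxygen import SaturationDistribution, integrate_vessel, extraction_rate

__all__ = [
    "PathRecord",
    "enumerate_paths",
    "integrate_paths",
    "weighted_mean",
    "weighted_sd",
    "weighted_cov",
    "compare_models",
    "correlation_suite",
    "HeterogeneitySummary",
]

PATH_CAP = 10_000


@dataclass
class PathRecord:
    """One inflow→outflow capillary path with its RBC-flow weight."""

    vessels: tuple[int, ...]
    weight: float
    transit_time: float = np.nan     # s
    length: float = np.nan           # μm
    S_a: float = np.nan
    S_v: float = np.nan

    @property
    def dS(self) -> float:
        return self.S_a - self.S_v


def enumerate_paths(net: CapillaryNetwork, cap: int = PATH_CAP) -> list[PathRecord]:
    """All directed inflow→outflow paths with RBC-flux weights.

    The weight of a path is its share of the total RBC flux: the inflow
    vessel's share of total inflow RBC flux times, at every diverging node
    encountered, the fraction of the RBC flux taken by the branch followed.
    Weights sum to 1. If the path count exceeds ``cap``, the smallest-weight
    paths are truncated and the rest renormalized (reported in the record
    count); transit time and length are accumulated per vessel.
    """
    # children of each vessel in flow direction, with RBC-flux fractions
    children: dict[int, list[tuple[int, float]]] = {}
    for vid, v in net.vessels.items():
        if not np.isfinite(v.q) or v.q == 0.0:
            continue
        node = net.nodes[v.downstream_node()]
        kids = [net.vessels[k] for k in node.vessel_ids
                if k != vid and np.isfinite(net.vessels[k].q)
                and net.vessels[k].q != 0.0
                and net.vessels[k].upstream_node() == node.id]
        total = sum(abs(k.q_rbc) for k in kids)
        children[vid] = ([(k.id, abs(k.q_rbc) / total) for k in kids]
                        if total > 0 else [])
    dg = net.directed_graph()
    if not nx.is_directed_acyclic_graph(dg):
        raise NetworkValidationError("flow graph contains a cycle")

    inflow = [vid for vid in net.inflow_vessels()
              if np.isfinite(net.vessels[vid].q) and net.vessels[vid].q != 0.0]
    total_in = sum(abs(net.vessels[v].q_rbc) for v in inflow)
    records: list[PathRecord] = []
    stack = [((vid,), abs(net.vessels[vid].q_rbc) / total_in) for vid in inflow]
    while stack:
        path, w = stack.pop()
        if w <= 0:
            continue
        kids = children.get(path[-1], [])
        if not kids:
            tau = sum(net.vessels[v].length / abs(net.vessels[v].v_rbc)
                      for v in path)
            length = sum(net.vessels[v].length for v in path)
            records.append(PathRecord(path, w, tau, length))
            if len(records) > 4 * cap:
                records.sort(key=lambda r: -r.weight)
                records = records[:cap]
            continue
        for kid, frac in kids:
            stack.append((path + (kid,), w * frac))
    if len(records) > cap:
        records.sort(key=lambda r: -r.weight)
        records = records[:cap]
    total_w = sum(r.weight for r in records)
    for r in records:
        r.weight /= total_w
    return records


def integrate_paths(net: CapillaryNetwork, paths: list[PathRecord],
                    inflow_S: dict[int, float], radii: dict[int, float],
                    params: OxygenParameters,
                    settings: SolverSettings | None = None) -> list[PathRecord]:
    """Fill in S_a/S_v by integrating the saturation balance along each path
    as a single unmixed stream (the per-path view of the ODE model)."""
    settings = settings or SolverSettings()
    for r in paths:
        s = inflow_S[r.vessels[0]]
        r.S_a = s
        for vid in r.vessels:
            v = net.vessels[vid]
            jt = extraction_rate(max(radii[vid], v.r_w), v.r_w, params.M0)
            prof = integrate_vessel(SaturationDistribution.delta(s), v, jt,
                                    params, settings)
            s = float(prof.S_atoms[0, -1])
        r.S_v = s
    return paths


def records_from_particles(path_records: "pd.DataFrame") -> list[PathRecord]:
    """PathRecords from per-RBC outflow rows (equal weight per RBC, which is
    RBC-flow weighting by construction)."""
    n = len(path_records)
    return [PathRecord(tuple(r.path), 1.0 / n, r.transit_time, r.path_length,
                       r.S_in, r.S_out)
            for r in path_records.itertuples()]


# ------------------------------------------------------------ weighted stats


def weighted_mean(values, weights) -> float:
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return float(np.sum(w * v) / w.sum())


def weighted_sd(values, weights) -> float:
    """Population-style weighted SD: sqrt(Σw(v − v̄)²/Σw)."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    m = weighted_mean(v, w)
    return float(np.sqrt(np.sum(w * (v - m) ** 2) / w.sum()))


def weighted_cov(values, weights) -> float:
    m = weighted_mean(values, weights)
    if m == 0:
        return np.nan
    return weighted_sd(values, weights) / abs(m)


# ------------------------------------------------------------------ summaries


@dataclass
class HeterogeneitySummary:
    cosh: float
    mean_S_v: float
    cth: float
    mean_transit: float
    cov_dS: float
    cov_transit: float
    frac_low_S: float                      # fraction of RBC flow with S_v < 0.2
    correlations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in vars(self).items() if k != "correlations"}
        for name, (r, p) in self.correlations.items():
            out[f"r_{name}"] = r
            out[f"p_{name}"] = p
        return out


def _pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) < 1e-15 or np.std(y[ok]) < 1e-15:
        return np.nan, np.nan
    res = stats.pearsonr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def correlation_suite(paths: list[PathRecord],
                      territories: pd.DataFrame | None = None,
                      net: CapillaryNetwork | None = None,
                      vessel_S: dict[int, float] | None = None,
                      low_S: float = 0.2) -> HeterogeneitySummary:
    """Heterogeneity summary with the standard correlation battery.

    Path-level: ΔS vs transit time and vs path length (flow-weighted
    moments, unweighted Pearson r as is conventional). Vessel-level (when a
    territory table and network are given): functional vs geometric radius,
    functional radius vs mean vessel saturation and vs RBC flow; plus an
    F-test on the two radius variances.
    """
    if len(paths) < 3:
        raise ValueError("need at least 3 paths")
    w = np.array([p.weight for p in paths])
    dS = np.array([p.dS for p in paths])
    S_v = np.array([p.S_v for p in paths])
    tau = np.array([p.transit_time for p in paths])
    length = np.array([p.length for p in paths])
    corr = {
        "dS_transit": _pearson(tau, dS),
        "dS_length": _pearson(length, dS),
    }
    if territories is not None and net is not None:
        ok = territories[np.isfinite(territories["r_t_fun"])
                         & (territories["flag"] == "")]
        r_fun = ok["r_t_fun"].to_numpy()
        r_geo = ok["r_t_geo"].to_numpy()
        corr["fun_geo"] = _pearson(r_geo, r_fun)
        flow = np.array([abs(net.vessels[v].q_rbc) for v in ok.index])
        corr["fun_flow"] = _pearson(flow, r_fun)
        if vessel_S is not None:
            sbar = np.array([vessel_S.get(v, np.nan) for v in ok.index])
            corr["fun_S"] = _pearson(sbar, r_fun)
        # two-sided F-test on SD(r_fun) vs SD(r_geo)
        if len(ok) > 2:
            f = np.var(r_fun, ddof=1) / np.var(r_geo, ddof=1)
            dfn = dfd = len(ok) - 1
            p = 2 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
            corr["f_test_radii"] = (float(f), float(p))
    return HeterogeneitySummary(
        cosh=weighted_sd(S_v, w),
        mean_S_v=weighted_mean(S_v, w),
        cth=weighted_sd(tau, w),
        mean_transit=weighted_mean(tau, w),
        cov_dS=weighted_cov(dS, w),
        cov_transit=weighted_cov(tau, w),
        frac_low_S=float(np.sum(w[S_v < low_S]) / np.sum(w)),
        correlations=corr,
    )


def compare_models(cosh_geometric: float, cosh_functional: float,
                   cosh_lagrangian: float) -> dict:
    """COSH per model and the diffusive-interaction decomposition.

    reduction = (COSH_no_interaction − COSH_full)/COSH_no_interaction; the
    geometric→functional step is the capillary-interaction share and the
    functional→Lagrangian step the RBC-interaction share of that reduction.
    """
    if cosh_geometric <= 0:
        raise ValueError("geometric COSH must be positive")
    total = cosh_geometric - cosh_lagrangian
    out = {
        "cosh_geometric": cosh_geometric,
        "cosh_functional": cosh_functional,
        "cosh_lagrangian": cosh_lagrangian,
        "reduction_percent": 100.0 * total / cosh_geometric,
        "reduction_functional_percent":
            100.0 * (cosh_geometric - cosh_functional) / cosh_geometric,
    }
    if total > 0:
        out["capillary_share"] = (cosh_geometric - cosh_functional) / total
        out["rbc_share"] = (cosh_functional - cosh_lagrangian) / total
    return out
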