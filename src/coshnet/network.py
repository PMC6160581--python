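"""Capillary network data model, validation, I/O and geometric preprocessing.

A network is a graph of vessels (edges, with 3-D polyline centerlines and
uniform per-vessel properties) joining nodes. Coordinates are in μm,
right-handed, origin at the bounding-box corner. Vessel orientation is
node_a → node_b and all signed flow quantities are relative to it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "Vessel",
    "NetworkNode",
    "CapillaryNetwork",
    "NetworkParseError",
    "NetworkValidationError",
    "load_network",
    "save_network",
]

RBC_RADIUS_RATIO = 0.8     # r_c = 0.8 r_p
WALL_RADIUS_RATIO = 1.25   # r_w = 1.25 r_p
RBC_DIAMETER_MIN = 3.0     # μm, clamp on 2 r_c
RBC_DIAMETER_MAX = 8.0


class NetworkParseError(ValueError):
    """Raised when network files are malformed or internally inconsistent."""


class NetworkValidationError(ValueError):
    """Raised when a parsed network violates a structural invariant."""


def _arc_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


@dataclass
class Vessel:
    """A capillary segment with uniform properties along its centerline."""

    id: int
    node_a: int
    node_b: int
    centerline: np.ndarray            # (k, 3) μm, from node_a to node_b
    diameter: float                   # lumen diameter, μm (= 2 r_p)
    # geometric radii, set by CapillaryNetwork.derive_radii
    r_p: float = np.nan
    r_c: float = np.nan
    r_w: float = np.nan
    # flow state, set by the flow solver
    q: float = np.nan                 # volumetric flow, μm³/s, signed a→b
    v_rbc: float = np.nan             # RBC velocity, μm/s, signed a→b
    H_T: float = np.nan               # tube hematocrit
    mu_LD: float = np.nan             # linear density
    q_rbc: float = np.nan             # RBC volume flux, μm³/s, signed a→b

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if len(self.centerline) < 2:
            raise NetworkParseError(f"vessel {self.id}: centerline needs ≥ 2 points")

    @property
    def length(self) -> float:
        """Arc length of the centerline, μm (cached; centerlines are
        immutable after construction)."""
        if not hasattr(self, "_length"):
            self._length = _arc_length(self.centerline)
        return self._length

    @property
    def lumen_area(self) -> float:
        return np.pi * self.r_p**2

    def upstream_node(self) -> int:
        if not np.isfinite(self.q):
            raise NetworkValidationError(f"vessel {self.id}: flow not set")
        return self.node_a if self.q >= 0 else self.node_b

    def downstream_node(self) -> int:
        return self.node_b if self.q >= 0 else self.node_a


@dataclass
class NetworkNode:
    id: int
    position: np.ndarray              # (3,) μm
    vessel_ids: list[int] = field(default_factory=list)
    boundary_kind: str = "interior"   # interior | inflow | outflow

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)

    @property
    def degree(self) -> int:
        return len(self.vessel_ids)

    @property
    def is_boundary(self) -> bool:
        return self.boundary_kind != "interior"


class CapillaryNetwork:
    """Vessels + nodes with validation and geometric preprocessing."""

    def __init__(self, vessels: dict[int, Vessel], nodes: dict[int, NetworkNode],
                 bounding_box: np.ndarray | None = None):
        self.vessels = dict(sorted(vessels.items()))
        self.nodes = dict(sorted(nodes.items()))
        for node in self.nodes.values():
            node.vessel_ids = []
        for v in self.vessels.values():
            for nid in (v.node_a, v.node_b):
                if nid not in self.nodes:
                    raise NetworkParseError(
                        f"vessel {v.id} references unknown node id {nid}")
                self.nodes[nid].vessel_ids.append(v.id)
        if bounding_box is None:
            pts = np.vstack([v.centerline for v in self.vessels.values()])
            bounding_box = np.stack([pts.min(axis=0), pts.max(axis=0)])
        self.bounding_box = np.asarray(bounding_box, dtype=float).reshape(2, 3)

    # ------------------------------------------------------------------ basics
    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def vessel_ids(self) -> list[int]:
        return list(self.vessels)

    def boundary_nodes(self, kind: str | None = None) -> list[int]:
        return [n.id for n in self.nodes.values()
                if (n.is_boundary if kind is None else n.boundary_kind == kind)]

    def inflow_vessels(self) -> list[int]:
        """Vessels through which blood enters the network.

        With solved flow, these are the vessels whose upstream node is a
        boundary node (functional definition — a reconstructed flow may
        reverse a nominal boundary role); without flow, the inflow labels
        are used."""
        out = set()
        for nid in self.boundary_nodes():
            for vid in self.nodes[nid].vessel_ids:
                v = self.vessels[vid]
                if np.isfinite(v.q) and v.q != 0.0:
                    if v.upstream_node() == nid:
                        out.add(vid)
                elif self.nodes[nid].boundary_kind == "inflow":
                    out.add(vid)
        return sorted(out)

    def outflow_vessels(self) -> list[int]:
        """Vessels through which blood leaves (see :meth:`inflow_vessels`)."""
        out = set()
        for nid in self.boundary_nodes():
            for vid in self.nodes[nid].vessel_ids:
                v = self.vessels[vid]
                if np.isfinite(v.q) and v.q != 0.0:
                    if v.downstream_node() == nid:
                        out.add(vid)
                elif self.nodes[nid].boundary_kind == "outflow":
                    out.add(vid)
        return sorted(out)

    def to_graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for v in self.vessels.values():
            g.add_edge(v.node_a, v.node_b, key=v.id)
        return g

    def directed_graph(self) -> nx.MultiDiGraph:
        """Directed graph induced by flow signs; zero-flow vessels excluded."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for v in self.vessels.values():
            if np.isfinite(v.q) and v.q != 0.0:
                g.add_edge(v.upstream_node(), v.downstream_node(), key=v.id)
        return g

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        g = self.to_graph()
        if self.n_vessels and not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise NetworkValidationError(
                f"network is disconnected: {len(comps)} components, e.g. {comps[:3]}")
        for v in self.vessels.values():
            if v.node_a == v.node_b:
                raise NetworkValidationError(f"vessel {v.id} is a self-loop")
            for nid, end in ((v.node_a, 0), (v.node_b, -1)):
                if not np.allclose(v.centerline[end], self.nodes[nid].position, atol=1e-6):
                    raise NetworkValidationError(
                        f"vessel {v.id}: centerline end does not match node {nid}")
        for n in self.nodes.values():
            if n.boundary_kind == "interior" and n.degree < 2:
                raise NetworkValidationError(
                    f"interior node {n.id} has degree {n.degree} < 2")
            if n.is_boundary and n.degree != 1:
                raise NetworkValidationError(
                    f"boundary node {n.id} has degree {n.degree} != 1")

    # ---------------------------------------------------------- preprocessing
    def rescale_diameters(self, target_mean: float = 5.0, target_sd: float = 1.5,
                          floor: float = 3.0) -> dict:
        """Affinely rescale the diameter distribution, then clamp at ``floor``.

        Returns the achieved mean/SD after clamping. A zero-variance input
        distribution is mapped to the constant ``target_mean`` with a warning.
        """
        if not target_mean > floor > 0:
            raise ValueError("require target_mean > floor > 0")
        d = np.array([v.diameter for v in self.vessels.values()])
        sd = d.std()
        if sd < 1e-12:
            warnings.warn("degenerate diameter distribution; setting all to target mean")
            new = np.full_like(d, target_mean)
        else:
            new = target_mean + (d - d.mean()) * (target_sd / sd)
        new = np.maximum(new, floor)
        for v, di in zip(self.vessels.values(), new):
            v.diameter = float(di)
        if hasattr(self, "_geom_cache"):
            del self._geom_cache
        return {"mean": float(new.mean()), "sd": float(new.std())}

    def derive_radii(self, r_c_ratio: float = RBC_RADIUS_RATIO,
                     r_w_ratio: float = WALL_RADIUS_RATIO,
                     rbc_d_min: float = RBC_DIAMETER_MIN,
                     rbc_d_max: float = RBC_DIAMETER_MAX) -> None:
        """Set plasma, RBC and endothelium radii from the lumen diameter.

        r_p = d/2, r_c = r_c_ratio·r_p with the RBC diameter 2 r_c clamped to
        [rbc_d_min, rbc_d_max] μm, r_w = r_w_ratio·r_p.
        """
        for v in self.vessels.values():
            v.r_p = v.diameter / 2.0
            v.r_c = float(np.clip(r_c_ratio * v.r_p, rbc_d_min / 2.0, rbc_d_max / 2.0))
            v.r_w = r_w_ratio * v.r_p

    def classify_bifurcations(self) -> dict[int, str]:
        """Classify each vessel as inflow / after_converging / other.

        A vessel is "after_converging" iff ≥ 2 vessels flow into its upstream
        node. Requires solved flow; zero-flow vessels are classified "other".
        """
        in_count: dict[int, int] = {nid: 0 for nid in self.nodes}
        for v in self.vessels.values():
            if np.isfinite(v.q) and v.q != 0.0:
                in_count[v.downstream_node()] += 1
        labels = {}
        for v in self.vessels.values():
            if not np.isfinite(v.q) or v.q == 0.0:
                labels[v.id] = "other"
                continue
            up = v.upstream_node()
            if self.nodes[up].boundary_kind == "inflow":
                labels[v.id] = "inflow"
            elif in_count[up] >= 2:
                labels[v.id] = "after_converging"
            else:
                labels[v.id] = "other"
        return labels

    def n_converging_bifurcations(self) -> int:
        """Interior nodes receiving flow from ≥ 2 vessels."""
        in_count: dict[int, int] = {nid: 0 for nid in self.nodes}
        for v in self.vessels.values():
            if np.isfinite(v.q) and v.q != 0.0:
                in_count[v.downstream_node()] += 1
        return sum(1 for nid, c in in_count.items()
                   if c >= 2 and self.nodes[nid].boundary_kind == "interior")

    # ------------------------------------------------------------------- I/O
    FLOW_COLUMNS = ("q", "v_rbc", "H_T", "mu_LD", "q_rbc")

    def to_dict(self) -> dict:
        return {
            "bounding_box": self.bounding_box.tolist(),
            "nodes": [
                {"id": n.id, "position": n.position.tolist(),
                 "boundary_kind": n.boundary_kind}
                for n in self.nodes.values()
            ],
            "vessels": [
                {"id": v.id, "node_a": v.node_a, "node_b": v.node_b,
                 "diameter": v.diameter, "centerline": v.centerline.tolist(),
                 **{c: getattr(v, c) for c in ("r_p", "r_c", "r_w") + self.FLOW_COLUMNS
                    if np.isfinite(getattr(v, c))}}
                for v in self.vessels.values()
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CapillaryNetwork":
        nodes, vessels = {}, {}
        for rec in payload["nodes"]:
            nid = int(rec["id"])
            if nid in nodes:
                raise NetworkParseError(f"duplicate node id {nid}")
            nodes[nid] = NetworkNode(nid, rec["position"],
                                     boundary_kind=rec.get("boundary_kind", "interior"))
        for rec in payload["vessels"]:
            vid = int(rec["id"])
            if vid in vessels:
                raise NetworkParseError(f"duplicate vessel id {vid}")
            v = Vessel(vid, int(rec["node_a"]), int(rec["node_b"]),
                       np.asarray(rec["centerline"]), float(rec["diameter"]))
            for c in ("r_p", "r_c", "r_w") + cls.FLOW_COLUMNS:
                if c in rec:
                    setattr(v, c, float(rec[c]))
            vessels[vid] = v
        return cls(vessels, nodes, np.asarray(payload.get("bounding_box")))

    def save(self, path: str | Path, format: str | None = None) -> None:
        save_network(self, path, format)

    # ------------------------------------------------------------ VTK export
    def to_vtk(self, path: str | Path) -> None:
        """Write-only legacy-ASCII VTK polydata export with per-vessel scalars."""
        lines = ["# vtk DataFile Version 3.0", "capillary network", "ASCII",
                 "DATASET POLYDATA"]
        points, offsets = [], []
        for v in self.vessels.values():
            offsets.append((len(points), len(v.centerline)))
            points.extend(v.centerline.tolist())
        lines.append(f"POINTS {len(points)} float")
        lines.extend(" ".join(f"{c:.6g}" for c in p) for p in points)
        size = sum(n + 1 for _, n in offsets)
        lines.append(f"LINES {len(offsets)} {size}")
        for start, n in offsets:
            lines.append(" ".join(map(str, [n] + list(range(start, start + n)))))
        lines.append(f"CELL_DATA {len(offsets)}")
        for name in ("diameter",) + self.FLOW_COLUMNS:
            vals = [getattr(v, name) for v in self.vessels.values()]
            if name != "diameter" and not np.any(np.isfinite(vals)):
                continue
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{np.nan_to_num(x):.6g}" for x in vals)
        Path(path).write_text("\n".join(lines) + "\n")


def save_network(net: CapillaryNetwork, path: str | Path, format: str | None = None) -> None:
    """Save to single-file JSON (``*.json``) or a nodes/edges CSV pair.

    The CSV pair is ``<stem>_nodes.csv`` / ``<stem>_edges.csv`` plus a sidecar
    ``<stem>_centerlines.json`` holding the packed polylines.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    payload = net.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(payload))
        return
    stem = path.with_suffix("")
    pd.DataFrame(
        [{"id": n["id"], "x": n["position"][0], "y": n["position"][1],
          "z": n["position"][2], "boundary_kind": n["boundary_kind"]}
         for n in payload["nodes"]]
    ).to_csv(f"{stem}_nodes.csv", index=False)
    edge_rows = []
    centerlines = {}
    for v in payload["vessels"]:
        row = {k: v[k] for k in v if k != "centerline"}
        edge_rows.append(row)
        centerlines[str(v["id"])] = v["centerline"]
    pd.DataFrame(edge_rows).to_csv(f"{stem}_edges.csv", index=False)
    Path(f"{stem}_centerlines.json").write_text(
        json.dumps({"bounding_box": payload["bounding_box"], "polylines": centerlines}))


def load_network(path: str | Path, format: str | None = None) -> CapillaryNetwork:
    """Load a network from JSON or a nodes/edges CSV pair and validate it."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "json":
        if not path.exists():
            raise NetworkParseError(f"no such file: {path}")
        payload = json.loads(path.read_text())
    else:
        stem = path.with_suffix("")
        for suffix in ("_nodes.csv", "_edges.csv", "_centerlines.json"):
            if not Path(f"{stem}{suffix}").exists():
                raise NetworkParseError(f"missing file: {stem}{suffix}")
        nodes_df = pd.read_csv(f"{stem}_nodes.csv")
        edges_df = pd.read_csv(f"{stem}_edges.csv")
        sidecar = json.loads(Path(f"{stem}_centerlines.json").read_text())
        payload = {
            "bounding_box": sidecar.get("bounding_box"),
            "nodes": [{"id": int(r.id), "position": [r.x, r.y, r.z],
                       "boundary_kind": r.boundary_kind}
                      for r in nodes_df.itertuples()],
            "vessels": [],
        }
        for r in edges_df.to_dict("records"):
            key = str(int(r["id"]))
            if key not in sidecar["polylines"]:
                raise NetworkParseError(f"vessel {key}: no centerline in sidecar")
            rec = {k: r[k] for k in r if not (isinstance(r[k], float) and np.isnan(r[k]))}
            rec["centerline"] = sidecar["polylines"][key]
            payload["vessels"].append(rec)
    net = CapillaryNetwork.from_dict(payload)
    net.validate()
    return net
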