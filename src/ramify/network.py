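"""Network dictionary and graph topology analysis.

During growth the network is a dictionary of typed nodes (seed, branch,
bifurcation, merge, terminal) and polyline edges. Edges are *open* while a
cone is still extending them (no end node yet) and are closed by events or at
finalization. Merging splits the target edge at the matched sample point;
the old edge key is kept as an alias to its two halves so stale occupancy
labels stay resolvable.

For analysis the dictionary is converted to a networkx graph, nearby nodes
are consolidated (mimicking finite imaging resolution), and standard
topology metrics are computed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger("ramify.network")

__all__ = [
    "Node",
    "Edge",
    "NetworkState",
    "NetworkIntegrityError",
    "TopologyReport",
    "build_graph",
    "merge_close_nodes",
    "topology_metrics",
    "giant_component_history",
    "save_graphml",
    "load_graphml",
    "export_swc",
    "load_swc",
]

NODE_KINDS = ("seed", "branch", "bifurcation", "merge", "terminal")


class NetworkIntegrityError(RuntimeError):
    pass


@dataclass
class Node:
    key: str
    position: np.ndarray
    kind: str
    birth_step: int = 0


@dataclass
class Edge:
    key: str
    points: list = field(default_factory=list)  # list of (3,) arrays
    u: str | None = None   # start node key
    v: str | None = None   # end node key (None while open)
    cone: str | None = None

    @property
    def closed(self) -> bool:
        return self.v is not None

    def points_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 3)

    def arc_length(self) -> float:
        pts = self.points_array()
        if len(pts) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


class NetworkState:
    """Node/edge dictionary with split aliases."""

    def __init__(self):
        self.nodes: dict[str, Node] = {}
        self.edges: dict[str, Edge] = {}
        self.aliases: dict[str, tuple[str, str]] = {}

    def add_node(self, key: str, position, kind: str, birth_step: int = 0) -> Node:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        node = Node(key, np.asarray(position, float).copy(), kind, birth_step)
        self.nodes[key] = node
        return node

    def add_edge(self, key: str, u: str, points, cone: str | None = None) -> Edge:
        edge = Edge(key, [np.asarray(p, float).copy() for p in points], u=u,
                    cone=cone)
        self.edges[key] = edge
        return edge

    def close_edge(self, key: str, v: str) -> None:
        self.edges[key].v = v

    def resolve_edge(self, key: str) -> list[Edge]:
        """Follow split aliases down to the live edges behind a (possibly
        stale) occupancy label."""
        if key in self.edges:
            return [self.edges[key]]
        if key in self.aliases:
            out = []
            for k in self.aliases[key]:
                out.extend(self.resolve_edge(k))
            return out
        return []

    def split_edge(self, key: str, index: int, node_key: str) -> tuple[str, str]:
        """Split an edge at sample ``index`` (where the new node sits).

        The first half is closed between the original start node and the new
        node; the second half keeps the original end node (or stays open and
        is handed back to its growing cone). Returns the two new keys.
        """
        edge = self.edges.pop(key)
        if not 0 < index < len(edge.points) - (0 if edge.v is None else 1):
            # splitting exactly at an endpoint is the caller's job to avoid
            raise ValueError(f"cannot split edge {key} at sample {index}")
        k1, k2 = key + "#0", key + "#1"
        first = Edge(k1, edge.points[: index + 1], u=edge.u, v=node_key,
                     cone=edge.cone)
        second = Edge(k2, edge.points[index:], u=node_key, v=edge.v,
                      cone=edge.cone)
        self.edges[k1] = first
        self.edges[k2] = second
        self.aliases[key] = (k1, k2)
        return k1, k2

    def closed_edges(self) -> list[Edge]:
        return [e for e in self.edges.values() if e.closed]

    def snapshot(self) -> "NetworkState":
        """Lightweight topological copy: all nodes, closed edges with their
        endpoints only (polylines reduced to first/last point)."""
        snap = NetworkState()
        for n in self.nodes.values():
            snap.add_node(n.key, n.position, n.kind, n.birth_step)
        for e in self.closed_edges():
            se = Edge(e.key, [e.points[0], e.points[-1]], u=e.u, v=e.v,
                      cone=e.cone)
            snap.edges[e.key] = se
        return snap

    def seed_node_keys(self) -> list[str]:
        return sorted(k for k, n in self.nodes.items() if n.kind == "seed")


# ---------------------------------------------------------------------------
# Graph construction and consolidation
# ---------------------------------------------------------------------------

def build_graph(state: NetworkState) -> nx.MultiGraph:
    """One graph node per network node, one graph edge per closed network
    edge, with polyline arc length as edge attribute. Self-loops occur only
    when a cone merged with its own earlier trajectory."""
    G = nx.MultiGraph()
    for node in state.nodes.values():
        G.add_node(node.key, position=tuple(node.position), kind=node.kind,
                   birth_step=node.birth_step)
    for edge in state.closed_edges():
        for end in (edge.u, edge.v):
            if end not in state.nodes:
                raise NetworkIntegrityError(
                    f"edge {edge.key} references missing node {end}")
        G.add_edge(edge.u, edge.v, key=edge.key, length=edge.arc_length(),
                   n_points=len(edge.points))
    return G


def merge_close_nodes(G: nx.Graph, resolution: float) -> nx.Graph:
    """Consolidate nodes closer than ``resolution`` (single linkage).

    Groups of nearby nodes collapse to one node at the group centroid;
    parallel edges collapse keeping the minimum length; self-loops shorter
    than the resolution are dropped. ``resolution == 0`` returns a copy.
    """
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    if resolution == 0:
        return G.copy()
    from scipy.spatial import cKDTree

    keys = sorted(G.nodes)
    pos = np.array([G.nodes[k]["position"] for k in keys], dtype=float)
    uf = nx.utils.UnionFind(keys)
    if len(keys) > 1:
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(resolution):
            uf.union(keys[i], keys[j])
    groups: dict[str, list[str]] = {}
    for k in keys:
        groups.setdefault(uf[k], []).append(k)
    super_of = {}
    H = nx.Graph()
    for members in groups.values():
        rep = min(members)
        centroid = np.mean([G.nodes[m]["position"] for m in members], axis=0)
        kinds = sorted({G.nodes[m].get("kind", "terminal") for m in members})
        H.add_node(rep, position=tuple(centroid),
                   kind=kinds[0] if len(kinds) == 1 else "merge",
                   n_members=len(members))
        for m in members:
            super_of[m] = rep
    for u, v, data in G.edges(data=True):
        su, sv = super_of[u], super_of[v]
        length = float(data.get("length", 1.0))
        if su == sv:
            if length < resolution:
                continue
            # long self-loop survives consolidation
        if H.has_edge(su, sv):
            if length < H[su][sv]["length"]:
                H[su][sv]["length"] = length
        else:
            H.add_edge(su, sv, length=length)
    return H


# ---------------------------------------------------------------------------
# Topology metrics
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    """Global topology summary: node count N, mean degree <k>, mean local
    clustering <cc>, average shortest path on the largest component (hops),
    edge density d, mean normalized betweenness <C_B>, mean current-flow
    (information) centrality <C_I> on the largest component, mean harmonic
    centrality <C_H> normalized by N-1, and the giant-component fraction."""

    n_nodes: int = 0
    avg_degree: float = 0.0
    clustering: float = 0.0
    avg_shortest_path: float = 0.0
    density: float = 0.0
    betweenness: float = 0.0
    information: float = 0.0
    harmonic: float = 0.0
    giant_fraction: float = 0.0
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "N": self.n_nodes, "avg_degree": self.avg_degree,
            "clustering": self.clustering, "asp": self.avg_shortest_path,
            "density": self.density, "betweenness": self.betweenness,
            "information": self.information, "harmonic": self.harmonic,
            "giant_fraction": self.giant_fraction,
        }


def _as_simple(G: nx.Graph) -> nx.Graph:
    if not G.is_multigraph():
        return G
    H = nx.Graph()
    H.add_nodes_from(G.nodes(data=True))
    for u, v, data in G.edges(data=True):
        length = float(data.get("length", 1.0))
        if H.has_edge(u, v):
            H[u][v]["length"] = min(H[u][v]["length"], length)
        else:
            H.add_edge(u, v, length=length)
    return H


def topology_metrics(G: nx.Graph, include_centralities: bool = True) -> TopologyReport:
    """Compute the global topology report (unweighted hop metrics).

    Path-based quantities (ASP, information centrality) are evaluated on the
    largest connected component and reported alongside the giant-component
    fraction; centralities can be skipped for speed in large sweeps.
    """
    G = _as_simple(G)
    n = G.number_of_nodes()
    if n == 0:
        return TopologyReport(empty=True)
    H = G.copy()
    H.remove_edges_from(nx.selfloop_edges(H))
    e = H.number_of_edges()
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.average_clustering(H) if n > 0 else 0.0
    comps = sorted(nx.connected_components(H), key=len, reverse=True)
    giant = H.subgraph(comps[0])
    giant_fraction = giant.number_of_nodes() / n
    asp = (nx.average_shortest_path_length(giant)
           if giant.number_of_nodes() > 1 else 0.0)
    betw = info = harm = 0.0
    if include_centralities:
        betw = float(np.mean(list(nx.betweenness_centrality(H, normalized=True)
                                  .values())))
        if giant.number_of_nodes() > 1:
            info = float(np.mean(list(
                nx.information_centrality(giant).values())))
        harm = float(np.mean(list(nx.harmonic_centrality(H).values())))
        if n > 1:
            harm /= (n - 1)
    return TopologyReport(n, avg_degree, clustering, asp, density,
                          betw, info, harm, giant_fraction)


def giant_component_history(snapshots, seed_nodes) -> list[float]:
    """Fraction of seed nodes inside the largest connected component, per
    snapshot. Isolated seeds each form their own singleton component."""
    seed_nodes = list(seed_nodes)
    out = []
    for snap in snapshots:
        G = build_graph(snap) if isinstance(snap, NetworkState) else snap
        if G.number_of_nodes() == 0 or not seed_nodes:
            out.append(0.0)
            continue
        comps = sorted(nx.connected_components(G), key=len, reverse=True)
        best = 0
        for comp in comps:
            best = max(best, sum(1 for s in seed_nodes if s in comp))
        out.append(best / len(seed_nodes))
    return out


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def save_graphml(G: nx.Graph, path) -> None:
    """Write GraphML with node positions flattened to x/y/z attributes."""
    H = G.copy()
    for _, data in H.nodes(data=True):
        p = data.pop("position", None)
        if p is not None:
            data["x"], data["y"], data["z"] = (float(c) for c in p)
    nx.write_graphml(H, str(path))


def load_graphml(path) -> nx.Graph:
    G = nx.read_graphml(str(path))
    for _, data in G.nodes(data=True):
        if all(c in data for c in "xyz"):
            data["position"] = (data.pop("x"), data.pop("y"), data.pop("z"))
    return G


def export_swc(state: NetworkState, out_dir, radius: float = 0.5) -> list[Path]:
    """Write one SWC morphology file per seed-rooted tree.

    SWC encodes rooted trees only, so a breadth-first spanning tree from each
    seed node is exported; edges skipped because they close cycles or belong
    to another seed's tree are listed in a JSON cross-reference sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adjacency: dict[str, list[Edge]] = {}
    for e in state.closed_edges():
        adjacency.setdefault(e.u, []).append(e)
        adjacency.setdefault(e.v, []).append(e)
    written = []
    for seed in state.seed_node_keys():
        rows = []  # (index, type, x, y, z, radius, parent)
        skipped: list[str] = []
        counter = 1
        seen_nodes = {seed}
        seen_edges: set[str] = set()
        node_index = {}
        p = state.nodes[seed].position
        rows.append((counter, 1, *p, radius, -1))
        node_index[seed] = counter
        counter += 1
        queue = [seed]
        while queue:
            cur = queue.pop(0)
            for e in sorted(adjacency.get(cur, []), key=lambda e: e.key):
                if e.key in seen_edges:
                    continue
                seen_edges.add(e.key)
                other = e.v if e.u == cur else e.u
                if other in seen_nodes:
                    skipped.append(e.key)
                    continue
                pts = e.points_array()
                if e.u != cur:
                    pts = pts[::-1]
                parent = node_index[cur]
                for pt in pts[1:]:
                    rows.append((counter, 3, *pt, radius, parent))
                    parent = counter
                    counter += 1
                node_index[other] = parent
                seen_nodes.add(other)
                queue.append(other)
        path = out_dir / f"tree_{seed.replace(':', '_')}.swc"
        with open(path, "w") as fh:
            fh.write("# SWC export; seed-rooted spanning tree\n")
            for r in rows:
                fh.write(f"{r[0]} {r[1]} {r[2]:.6f} {r[3]:.6f} {r[4]:.6f} "
                         f"{r[5]:.3f} {r[6]}\n")
        if skipped:
            side = path.with_suffix(".crossrefs.json")
            side.write_text(json.dumps({"skipped_edges": sorted(skipped)},
                                       indent=2))
        written.append(path)
    return written


def load_swc(path) -> np.ndarray:
    """Read an SWC file back as an (n, 7) float array."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(tok) for tok in line.split()])
    return np.asarray(rows)


def report_to_csv(reports: list[TopologyReport], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(reports[0].to_dict()))
        writer.writeheader()
        for r in reports:
            writer.writerow(r.to_dict())
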