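"""Simulation orchestration: clustering, stepping, shared-state updates.

A run consists of ``n_updates`` global updates of ``steps_per_update`` growth
steps each. At every global update the active cones are partitioned into
interaction clusters by cutting Delaunay edges longer than ``l_d``; clusters
cannot interact for the duration of one update provided
``l_d >= 2 * s * l + 2 * R_c`` (each cone moves at most ``s * l``, contact
needs ``2 * R_c``), so they may be stepped independently — here sequentially,
but in an order-independent way.

Reproducibility is per-cone: every cone owns a counter-based random stream
derived from the master seed and its (deterministic) cone id, and every event
decision consumes a fixed number of draws. Running with clustering on or off
therefore produces bit-identical network dictionaries.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter, deque
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError

from .cones import (ConeParameters, GrowthCone, bifurcation_directions,
                    branch_direction, decide_event, advance)
from .environment import (DEFAULT_IMPRINT_RADIUS, EnvironmentStack,
                          required_search_field)
from .kernels import (build_angular_grid, drift_kernel, persistence_kernel,
                      random_walk_kernel, soluble_kernel, structure_kernel)
from .network import NetworkState

logger = logging.getLogger("ramify.engine")

__all__ = [
    "Seed",
    "SimulationConfig",
    "SimulationResult",
    "derive_rng_stream",
    "cluster_cones",
    "run_simulation",
]


@dataclass
class Seed:
    """Starting point of one growth process: position, initial unit
    direction, and the cell (seed node) it belongs to."""

    position: np.ndarray
    direction: np.ndarray
    cell: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("seed direction must be nonzero")
        self.direction = d / n


@dataclass
class SimulationConfig:
    """Run configuration: loop sizes, cue switches and weights, seeds.

    ``delaunay_distance`` defaults to the interaction-safety bound
    ``2 * steps_per_update * step_length + 2 * merge_radius``.
    """

    n_updates: int = 10
    steps_per_update: int = 25
    cone: ConeParameters = dc_field(default_factory=ConeParameters)
    master_seed: int = 0
    use_clustering: bool = True
    delaunay_distance: float | None = None
    sphere_nodes: int = 2000
    # cue families (switches + weights)
    use_random_walk: bool = True
    random_walk_sigma: float = 0.5
    use_persistence: bool = True
    persistence_sigma: float = 0.5
    use_structure: bool = False
    structure_channel: str = "structure"
    structure_alpha: float = 4.0
    structure_gain: float = 5.0
    use_soluble: bool = False
    soluble_channel: str = "cue"
    soluble_beta: float = 1.0
    soluble_gamma: float = 1.0
    soluble_attractive: bool = True
    use_drift: bool = False
    drift_vector: tuple = (0.0, 0.0, 0.0)
    # engine controls
    max_cones: int = 4000
    track_balance: bool = False
    imprint_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_updates < 1 or self.steps_per_update < 1:
            raise ValueError("n_updates and steps_per_update must be >= 1")
        bound = self.safety_bound()
        if self.delaunay_distance is None:
            self.delaunay_distance = bound
        elif self.delaunay_distance < bound:
            logger.warning(
                "delaunay_distance %.3g below interaction-safety bound %.3g",
                self.delaunay_distance, bound)

    def safety_bound(self) -> float:
        l_max = self.cone.step_length + 4.0 * self.cone.step_sigma
        return 2.0 * self.steps_per_update * l_max + 2.0 * self.cone.merge_radius


@dataclass
class SimulationResult:
    network: NetworkState
    snapshots: list
    cones: dict
    event_counts: Counter
    per_update_counts: list
    balance: list
    seed_nodes: list
    config: SimulationConfig


def derive_rng_stream(master_seed: int, stream_id: str) -> np.random.Generator:
    """Independent, stable random stream for a named entity.

    The stream is keyed by a SHA-256 digest of ``(master_seed, stream_id)``,
    so the same pair always yields the same stream and distinct ids yield
    statistically independent Philox streams.
    """
    digest = hashlib.sha256(f"{master_seed}|{stream_id}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                 *(int(w) for w in words)])
    return np.random.Generator(np.random.Philox(ss))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _linkage_labels(positions: np.ndarray, l_d: float) -> np.ndarray:
    n = len(positions)
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    i, j = np.nonzero(d2 <= l_d * l_d)
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    return connected_components(adj, directed=False)[1]


def cluster_cones(positions: np.ndarray, l_d: float) -> np.ndarray:
    """Partition points into interaction clusters: connected components of
    the Delaunay graph after cutting edges longer than ``l_d``.

    Because the Euclidean minimum spanning tree is a subgraph of the Delaunay
    triangulation, this equals single-linkage clustering at threshold ``l_d``
    for points in general position. Degenerate geometries (< 5 points,
    coplanar/collinear sets) fall back to the pairwise-distance graph, which
    realizes the same contract.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        return np.zeros(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    if n < 5:
        return _linkage_labels(positions, l_d)
    try:
        tri = Delaunay(positions)
    except QhullError:
        return _linkage_labels(positions, l_d)
    simplices = tri.simplices
    pairs = set()
    m = simplices.shape[1]
    for a in range(m):
        for b in range(a + 1, m):
            pairs.update(zip(simplices[:, a].tolist(), simplices[:, b].tolist()))
    i = np.array([p[0] for p in pairs], dtype=int)
    j = np.array([p[1] for p in pairs], dtype=int)
    keep = (np.linalg.norm(positions[i] - positions[j], axis=1) <= l_d)
    adj = coo_matrix((np.ones(keep.sum()), (i[keep], j[keep])), shape=(n, n))
    return connected_components(adj, directed=False)[1]


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

class _Runner:
    """Holds the shared state of one simulation run."""

    def __init__(self, config: SimulationConfig, env: EnvironmentStack,
                 seeds: Sequence[Seed]):
        self.config = config
        self.env = env
        self.sphere = build_angular_grid(config.sphere_nodes)
        self.network = NetworkState()
        self.cones: dict[str, GrowthCone] = {}
        self.counts: Counter = Counter()
        self.balance: list[dict] = []
        self.snapshots: list[NetworkState] = []
        self.per_update: list[Counter] = []
        self.active_growing = 0
        cone_p = config.cone
        self.search_field = max(cone_p.search_field,
                                required_search_field(cone_p.merge_radius))
        self.imprint_radius = (config.imprint_radius if config.imprint_radius
                               is not None else
                               max(DEFAULT_IMPRINT_RADIUS, cone_p.merge_radius))
        self.threshold2 = (2.0 * cone_p.merge_radius) ** 2
        self._needs_fields = config.use_structure or config.use_soluble
        self._init_seeds(seeds)

    # -- setup ----------------------------------------------------------

    def _init_seeds(self, seeds: Sequence[Seed]) -> None:
        for k, seed in enumerate(seeds):
            if not self.env.contains(seed.position):
                raise ValueError(f"seed {k} outside the volume")
            cell = seed.cell if seed.cell is not None else k
            node_key = f"n:seed:{cell}"
            if node_key not in self.network.nodes:
                self.network.add_node(node_key, seed.position, "seed", 0)
            cid = f"{k:04d}"
            cone = GrowthCone(
                cid, self.config.cone,
                derive_rng_stream(self.config.master_seed, f"cone:{cid}"),
                positions=[np.asarray(seed.position, float).copy()],
                directions=[seed.direction.copy()],
                first_node=node_key, last_node=node_key)
            self._start_edge(cone, node_key, 0)
            self.cones[cid] = cone
            self.counts["seed"] += 1
            self.active_growing += 1

    def _start_edge(self, cone: GrowthCone, node_key: str, gstep: int) -> None:
        key = f"e:{cone.cid}:{gstep}"
        self.network.add_edge(key, node_key, [cone.position], cone.cid)
        self.env.register_edge(key)
        self.env.imprint_segment(key, cone.position, cone.position,
                                 self.imprint_radius)
        cone.edge_key = key
        cone.remember_sample(key, 0)

    # -- cue kernels ----------------------------------------------------

    def _cue_kernels(self, cone: GrowthCone, cues):
        cfg = self.config
        ks = []
        if cfg.use_random_walk:
            ks.append(random_walk_kernel(cfg.random_walk_sigma))
        if cfg.use_persistence and cone.params.memory > 0 and cone.directions:
            ks.append(persistence_kernel(cone.directions, cone.params.memory,
                                         cfg.persistence_sigma))
        if cfg.use_structure:
            ks.append(structure_kernel(cues.tensors[cfg.structure_channel],
                                       cues.gradients[cfg.structure_channel],
                                       cfg.structure_alpha, cfg.structure_gain))
        if cfg.use_soluble:
            ks.append(soluble_kernel(cues.gradients[cfg.soluble_channel],
                                     cfg.soluble_beta, cfg.soluble_gamma,
                                     cfg.soluble_attractive))
        if cfg.use_drift:
            ks.append(drift_kernel(np.asarray(cfg.drift_vector, float)))
        if not ks:
            ks.append(random_walk_kernel(1.0))
        return ks

    # -- candidates -----------------------------------------------------

    def _collect_candidates(self, cone: GrowthCone, hits):
        """All edge sample points within merge contact range ``2 R_c``.

        Pre-filtering to the contact range (rather than taking a global
        minimum first) keeps the decision independent of edges laid down by
        other clusters just outside contact range, which the safety bound
        guarantees can never actually be reached.
        """
        pos = cone.position
        out = []
        for key in sorted(hits):
            for edge in self.network.resolve_edge(key):
                pts = edge.points_array()
                if len(pts) == 0:
                    continue
                d2 = np.sum((pts - pos) ** 2, axis=1)
                for i in np.flatnonzero(d2 <= self.threshold2):
                    out.append((edge.key, int(i), pts[i]))
        return out

    # -- events ---------------------------------------------------------

    def _spawn(self, mother: GrowthCone, node_key: str,
               direction: np.ndarray, gstep: int, child_idx: int,
               members: list) -> None:
        cid = f"{mother.cid}.{gstep}.{child_idx}"
        m = mother.params.memory
        dirs = [d.copy() for d in mother.directions[-m:]] if m > 0 else []
        dirs.append(np.asarray(direction, float))
        cone = GrowthCone(
            cid, mother.params,
            derive_rng_stream(self.config.master_seed, f"cone:{cid}"),
            positions=[mother.position.copy()], directions=dirs,
            first_node=node_key, last_node=node_key,
            recent=deque(mother.recent))
        self._start_edge(cone, node_key, gstep)
        self.cones[cid] = cone
        self.active_growing += 1
        members.append(cid)

    def _do_branch(self, cone: GrowthCone, gstep: int, members: list) -> None:
        node_key = f"n:{cone.cid}:{gstep}"
        self.network.add_node(node_key, cone.position, "branch", gstep)
        self.network.close_edge(cone.edge_key, node_key)
        d_new = branch_direction(cone.direction, cone.params.theta_bran_deg,
                                 cone.rng)
        self._start_edge(cone, node_key, gstep)
        cone.last_node = node_key
        self._spawn(cone, node_key, d_new, gstep, 0, members)
        self.counts["branch"] += 1

    def _do_bifurcate(self, cone: GrowthCone, gstep: int, members: list) -> None:
        node_key = f"n:{cone.cid}:{gstep}"
        self.network.add_node(node_key, cone.position, "bifurcation", gstep)
        self.network.close_edge(cone.edge_key, node_key)
        da, db = bifurcation_directions(cone.direction,
                                        cone.params.theta_bif_deg, cone.rng)
        self._spawn(cone, node_key, da, gstep, 0, members)
        self._spawn(cone, node_key, db, gstep, 1, members)
        cone.state = "terminated"
        cone.retired = True
        cone.last_node = node_key
        self.active_growing -= 1
        self.counts["bifurcate"] += 1

    def _do_terminate(self, cone: GrowthCone, gstep: int) -> None:
        edge = self.network.edges[cone.edge_key]
        if len(edge.points) >= 2:
            node_key = f"n:{cone.cid}:{gstep}"
            self.network.add_node(node_key, cone.position, "terminal", gstep)
            self.network.close_edge(cone.edge_key, node_key)
            cone.last_node = node_key
        else:
            # the cone never moved on this edge; drop the stub
            del self.network.edges[cone.edge_key]
            cone.edge_key = None
        cone.state = "terminated"
        self.active_growing -= 1
        self.counts["terminate"] += 1

    def _do_merge(self, cone: GrowthCone, target, gstep: int) -> None:
        key, idx, point = target
        edge = self.network.edges[key]
        npts = len(edge.points)
        if idx == 0:
            node_key = edge.u
            self.counts["merge_reused_node"] += 1
        elif edge.closed and idx == npts - 1:
            node_key = edge.v
            self.counts["merge_reused_node"] += 1
        else:
            node_key = f"n:{cone.cid}:{gstep}"
            self.network.add_node(node_key, point, "merge", gstep)
            k1, k2 = self.network.split_edge(key, idx, node_key)
            owner = self.cones.get(edge.cone)
            if owner is not None and owner.edge_key == key:
                owner.edge_key = k2
                owner.rebase_recent(key, k1, k2, idx)
        # close the incoming edge at the new node
        inc = self.network.edges[cone.edge_key]
        if not np.allclose(inc.points[-1], point):
            inc.points.append(np.asarray(point, float).copy())
            self.env.imprint_segment(cone.edge_key, cone.position, point,
                                     self.imprint_radius)
        self.network.close_edge(cone.edge_key, node_key)
        cone.state = "merged"
        cone.last_node = node_key
        self.active_growing -= 1
        self.counts["merge"] += 1

    # -- stepping -------------------------------------------------------

    def _step_cone(self, cid: str, gstep: int, members: list) -> None:
        cone = self.cones[cid]
        if cone.state == "terminated":
            if not cone.retired and cone.rng.random() < cone.params.p_reac:
                cone.state = "growing"
                self._start_edge(cone, cone.last_node, gstep)
                self.active_growing += 1
                self.counts["reactivate"] += 1
            return
        if cone.state != "growing":
            return
        if self._needs_fields:
            cues = self.env.sample_local_cues(cone.position, self.search_field)
            hits = cues.occupancy_hits
        else:
            cues = None
            hits = self.env.edges_near(cone.position, self.search_field)
        candidates = self._collect_candidates(cone, hits)
        allow_split = self.active_growing < self.config.max_cones
        outcome = decide_event(cone, candidates, cone.rng, allow_split)
        if outcome.event == "merge":
            self._do_merge(cone, outcome.merge_target, gstep)
        elif outcome.event == "bifurcate":
            self._do_bifurcate(cone, gstep, members)
        elif outcome.event == "branch":
            self._do_branch(cone, gstep, members)
        elif outcome.event == "terminate":
            self._do_terminate(cone, gstep)
        else:
            kernels = self._cue_kernels(cone, cues)
            res = advance(cone, kernels, self.env, self.sphere, cone.rng,
                          self.imprint_radius)
            if res == "grow":
                edge = self.network.edges[cone.edge_key]
                edge.points.append(cone.position.copy())
                cone.remember_sample(cone.edge_key, len(edge.points) - 1)
            else:
                self.active_growing -= 1
                self.counts["exit"] += 1

    def _record_balance(self) -> None:
        c = self.counts
        self.balance.append({
            "active": self.active_growing,
            "expected": (c["seed"] + c["branch"] + c["bifurcate"]
                         - c["merge"] - c["terminate"] + c["reactivate"]
                         - c["exit"]),
        })

    def run(self) -> SimulationResult:
        cfg = self.config
        for update in range(cfg.n_updates):
            eligible = sorted(
                cid for cid, c in self.cones.items()
                if c.state == "growing"
                or (c.state == "terminated" and not c.retired))
            if not any(self.cones[cid].state == "growing" for cid in eligible):
                logger.info("no growing cones left after update %d; stopping",
                            update)
                break
            before = Counter(self.counts)
            if cfg.use_clustering and len(eligible) > 1:
                pos = np.array([self.cones[c].position for c in eligible])
                labels = cluster_cones(pos, cfg.delaunay_distance)
                groups: dict[int, list[str]] = {}
                for cid, lab in zip(eligible, labels):
                    groups.setdefault(int(lab), []).append(cid)
                clusters = sorted(groups.values(), key=lambda g: min(g))
            else:
                clusters = [list(eligible)]
            for members in clusters:
                for t in range(cfg.steps_per_update):
                    gstep = update * cfg.steps_per_update + t + 1
                    for cid in sorted(members):
                        self._step_cone(cid, gstep, members)
                    if cfg.track_balance:
                        self._record_balance()
            self.per_update.append(self.counts - before)
            self.snapshots.append(self.network.snapshot())
        self._finalize()
        return SimulationResult(
            network=self.network, snapshots=self.snapshots, cones=self.cones,
            event_counts=self.counts, per_update_counts=self.per_update,
            balance=self.balance, seed_nodes=self.network.seed_node_keys(),
            config=cfg)

    def _finalize(self) -> None:
        """Close every still-open edge with a terminal node (frozen
        out-of-bounds cones keep their partial edge)."""
        for cid in sorted(self.cones):
            cone = self.cones[cid]
            key = cone.edge_key
            if key is None or key not in self.network.edges:
                continue
            edge = self.network.edges[key]
            if edge.closed:
                continue
            if len(edge.points) >= 2:
                node_key = f"n:{cid}:end"
                self.network.add_node(node_key, edge.points[-1], "terminal",
                                      self.config.n_updates
                                      * self.config.steps_per_update)
                self.network.close_edge(key, node_key)
                cone.last_node = node_key
            else:
                del self.network.edges[key]
                cone.edge_key = None


def run_simulation(config: SimulationConfig, env: EnvironmentStack,
                   seeds: Sequence[Seed]) -> SimulationResult:
    """Run a full growth simulation and return the network plus histories."""
    return _Runner(config, env, seeds).run()
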