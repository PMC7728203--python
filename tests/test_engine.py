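"""Simulation-engine tests: clustering, reproducibility, bookkeeping."""

from dataclasses import replace

import networkx as nx
import numpy as np
import pytest

from ramify.cones import ConeParameters
from ramify.engine import (Seed, SimulationConfig, cluster_cones,
                           derive_rng_stream, run_simulation)
from ramify.environment import EnvironmentStack
from ramify.network import build_graph


def flat_env(n=32):
    rng = np.random.default_rng(0)
    return EnvironmentStack({"structure": rng.random((n, n, n))},
                            structural=("structure",))


def base_config(**over):
    cone = over.pop("cone", None)
    cone_kwargs = {k: over.pop(k) for k in list(over)
                   if k in ConeParameters.__dataclass_fields__}
    if cone is None:
        cone = ConeParameters(**cone_kwargs)
    defaults = dict(n_updates=2, steps_per_update=10, sphere_nodes=500,
                    use_structure=False, master_seed=7)
    defaults.update(over)
    return SimulationConfig(cone=cone, **defaults)


def network_signature(state):
    """Canonical, comparison-friendly rendering of a network dictionary."""
    nodes = {k: (n.kind, tuple(np.round(n.position, 12)))
             for k, n in state.nodes.items()}
    edges = {k: (e.u, e.v, tuple(map(tuple, np.round(e.points_array(), 12))))
             for k, e in state.edges.items()}
    return nodes, edges


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def brute_single_linkage(points, l_d):
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= l_d:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def partitions_equal(a, b):
    seen = {}
    for x, y in zip(a, b):
        if x in seen:
            if seen[x] != y:
                return False
        else:
            seen[x] = y
    return len(set(seen.values())) == len(seen)


class TestClusterCones:
    def test_far_points_are_singletons(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]])
        labels = cluster_cones(pts, 2.0)
        assert len(set(labels)) == 3

    def test_chain_is_transitive(self):
        pts = np.array([[i * 1.5, 0, 0.0] for i in range(8)])
        labels = cluster_cones(pts, 2.0)
        assert len(set(labels)) == 1

    @pytest.mark.parametrize("seed,l_d", [(0, 1.0), (1, 2.0), (2, 3.5)])
    def test_matches_single_linkage(self, seed, l_d):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 12, size=(100, 3))
        assert partitions_equal(cluster_cones(pts, l_d),
                                brute_single_linkage(pts, l_d))

    def test_degenerate_coplanar_fallback(self):
        pts = np.zeros((8, 3))
        pts[:, 0] = np.arange(8) * 1.2  # collinear: Qhull cannot triangulate
        labels = cluster_cones(pts, 1.5)
        assert len(set(labels)) == 1


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------

class TestRngStreams:
    def test_same_id_same_stream(self):
        a = derive_rng_stream(5, "cone:0001").random(10)
        b = derive_rng_stream(5, "cone:0001").random(10)
        assert np.array_equal(a, b)

    def test_daughter_differs_from_mother(self):
        a = derive_rng_stream(5, "cone:0001").random(10)
        b = derive_rng_stream(5, "cone:0001.7.0").random(10)
        assert not np.array_equal(a, b)

    def test_cross_correlation_small(self):
        x = derive_rng_stream(3, "cone:0000").random(10_000) - 0.5
        y = derive_rng_stream(3, "cone:0001").random(10_000) - 0.5
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 0.05


# ---------------------------------------------------------------------------
# Simulation runs
# ---------------------------------------------------------------------------

class TestRunSimulation:
    def test_single_straight_edge(self):
        # one seed, no events, zero aperture: a straight 20-step edge
        cfg = base_config(p_bran=0, p_bif=0, p_term=0, p_reac=0,
                          aperture_deg=0.0, memory=0,
                          use_persistence=False)
        env = flat_env()
        res = run_simulation(cfg, env, [Seed([16, 16, 5], [0, 0, 1.0])])
        assert len(res.network.nodes) == 2
        assert len(res.network.edges) == 1
        edge = next(iter(res.network.edges.values()))
        assert len(edge.points) == 21
        assert edge.arc_length() == pytest.approx(20.0)
        # straight up to grid resolution: every step direction is identical
        steps = np.diff(edge.points_array(), axis=0)
        assert np.abs(steps - steps[0]).max() < 1e-9
        assert steps[0] @ np.array([0, 0, 1.0]) > 0.99

    def test_seed_outside_volume_rejected(self):
        with pytest.raises(ValueError):
            run_simulation(base_config(), flat_env(),
                           [Seed([40, 0, 0], [0, 0, 1.0])])

    def test_determinism_bit_identical(self):
        env_a, env_b = flat_env(), flat_env()
        seeds = [Seed([10, 16, 16], [1, 0, 0], cell=0),
                 Seed([22, 16, 16], [-1, 0, 0], cell=1),
                 Seed([16, 10, 16], [0, 1, 0], cell=2)]
        cfg = base_config(n_updates=3)
        ra = run_simulation(cfg, env_a, seeds)
        rb = run_simulation(cfg, env_b, seeds)
        assert network_signature(ra.network) == network_signature(rb.network)
        assert ra.event_counts == rb.event_counts

    def test_clustering_on_off_equivalence(self):
        """Cluster-parallel stepping must equal serial stepping exactly,
        given per-cone random streams and the interaction-safety bound."""
        seeds = [Seed([8, 8, 8], [1, 1, 0], cell=0),
                 Seed([24, 24, 24], [-1, 0, 1], cell=1),
                 Seed([8, 24, 8], [0, -1, 1], cell=2),
                 Seed([24, 8, 24], [0, 1, -1], cell=3)]
        cfg_on = base_config(n_updates=3, steps_per_update=5,
                             p_bran=0.05, p_bif=0.05, use_clustering=True)
        cfg_off = replace(cfg_on, use_clustering=False)
        ra = run_simulation(cfg_on, flat_env(), seeds)
        rb = run_simulation(cfg_off, flat_env(), seeds)
        assert network_signature(ra.network) == network_signature(rb.network)

    def test_monotone_growth(self):
        seeds = [Seed([16, 16, 8], [0, 0, 1.0], cell=0),
                 Seed([10, 16, 16], [1, 0, 0], cell=1)]
        cfg = base_config(n_updates=4, steps_per_update=6, p_bran=0.05)
        res = run_simulation(cfg, flat_env(), seeds)
        n_nodes = [len(s.nodes) for s in res.snapshots]
        n_edges = [len(s.edges) for s in res.snapshots]
        assert all(a <= b for a, b in zip(n_nodes, n_nodes[1:]))
        assert all(a <= b for a, b in zip(n_edges, n_edges[1:]))

    def test_no_events_gives_simple_paths(self):
        # without splitting and merging every tree is a path, degree <= 2
        cfg = base_config(p_bran=0, p_bif=0, p_term=0, p_merge=0.0,
                          n_updates=2, steps_per_update=8)
        seeds = [Seed([8 + 6 * i, 16, 16], [0, 0, 1.0], cell=i)
                 for i in range(3)]
        res = run_simulation(cfg, flat_env(), seeds)
        G = build_graph(res.network)
        assert max(dict(G.degree()).values()) <= 2

    def test_cone_count_conservation(self):
        cfg = base_config(n_updates=3, steps_per_update=8, p_bran=0.08,
                          p_bif=0.05, p_term=0.05, p_reac=0.05,
                          track_balance=True, use_clustering=False)
        seeds = [Seed([16 + 3 * np.cos(a), 16 + 3 * np.sin(a), 16],
                      [np.cos(a), np.sin(a), 0.3], cell=i)
                 for i, a in enumerate(np.linspace(0, 2 * np.pi, 8,
                                                   endpoint=False))]
        res = run_simulation(cfg, flat_env(), seeds)
        assert len(res.balance) > 0
        for entry in res.balance:
            assert entry["active"] == entry["expected"]

    def test_node_census_matches_event_log(self):
        cfg = base_config(n_updates=3, steps_per_update=10, p_bran=0.06,
                          p_bif=0.04)
        seeds = [Seed([10 + 4 * i, 16, 10], [0, 0.2, 1.0], cell=i)
                 for i in range(4)]
        res = run_simulation(cfg, flat_env(), seeds)
        kinds = {}
        for node in res.network.nodes.values():
            kinds[node.kind] = kinds.get(node.kind, 0) + 1
        c = res.event_counts
        assert kinds.get("branch", 0) == c.get("branch", 0)
        assert kinds.get("bifurcation", 0) == c.get("bifurcate", 0)
        # merges landing exactly on an existing node reuse it
        assert kinds.get("merge", 0) == (c.get("merge", 0)
                                         - c.get("merge_reused_node", 0))

    def test_two_cone_crossing_merge(self):
        """A cone hitting a previously laid straight edge creates one merge
        node of degree three and stops (event-replay scenario)."""
        cfg = base_config(p_bran=0, p_bif=0, p_term=0, aperture_deg=0.0,
                          memory=0, use_persistence=False,
                          n_updates=1, steps_per_update=20)
        env = flat_env()
        seeds = [Seed([5, 10, 16], [1, 0, 0], cell=0),    # runs along +x
                 Seed([10, 3, 16], [0, 1, 0], cell=1)]    # crosses it later
        res = run_simulation(cfg, env, seeds)
        assert res.event_counts.get("merge", 0) == 1
        assert res.cones["0001"].state == "merged"
        G = build_graph(res.network)
        merge_nodes = [n for n, d in G.nodes(data=True) if d["kind"] == "merge"]
        assert len(merge_nodes) == 1
        assert G.degree(merge_nodes[0]) == 3
        # contact near the geometric crossing, up to sphere-grid snap drift
        assert np.allclose(G.nodes[merge_nodes[0]]["position"], (10, 10, 16),
                           atol=1.0)

    def test_out_of_bounds_freezes_cone(self):
        cfg = base_config(p_bran=0, p_bif=0, p_term=0, aperture_deg=0.0,
                          memory=0, use_persistence=False,
                          n_updates=1, steps_per_update=20)
        res = run_simulation(cfg, flat_env(),
                             [Seed([16, 16, 25], [0, 0, 1.0])])
        cone = res.cones["0000"]
        assert cone.state == "out_of_bounds"
        assert res.event_counts["exit"] == 1
        # partial edge kept, endpoint inside the volume
        edge = next(iter(res.network.edges.values()))
        assert edge.closed
        assert edge.points_array()[-1, 2] <= 31

    def test_event_frequency_calibration(self):
        """Aggregate branch/bifurcation frequencies over many cone-steps
        track the configured per-step probabilities."""
        cfg = base_config(p_bran=0.02, p_bif=0.01, p_term=0, p_reac=0,
                          n_updates=2, steps_per_update=25, max_cones=10_000)
        seeds = [Seed([16 + 6 * np.cos(a), 16 + 6 * np.sin(a), 16],
                      [np.cos(a), np.sin(a), 0.0], cell=i)
                 for i, a in enumerate(np.linspace(0, 2 * np.pi, 20,
                                                   endpoint=False))]
        res = run_simulation(cfg, flat_env(), seeds)
        c = res.event_counts
        # growth steps + events executed by growing cones
        cone_steps = sum(len(cn.positions) - 1 for cn in res.cones.values())
        cone_steps += (c["branch"] + c["bifurcate"] + c["terminate"]
                       + c["merge"] + c["exit"])
        for name, p in (("branch", 0.02), ("bifurcate", 0.01)):
            expected = cone_steps * p
            se = np.sqrt(cone_steps * p * (1 - p))
            assert abs(c[name] - expected) < 4 * se
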