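"""Network dictionary, consolidation and topology-metric tests.

The metric cross-checks use hand-rolled oracles (all-pairs BFS, direct
triangle counting, exhaustive shortest-path enumeration, Laplacian
pseudo-inverse resistances) so the networkx-backed implementation is verified
against independent arithmetic.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from ramify.network import (NetworkState, build_graph, export_swc,
                            giant_component_history, load_graphml, load_swc,
                            merge_close_nodes, save_graphml, topology_metrics)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def bfs_distances(G, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in G[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_asp(G):
    comp = max(nx.connected_components(G), key=len)
    nodes = sorted(comp)
    total, pairs = 0, 0
    for s in nodes:
        d = bfs_distances(G.subgraph(comp), s)
        for t in nodes:
            if t != s:
                total += d[t]
                pairs += 1
    return total / pairs if pairs else 0.0


def oracle_clustering(G):
    vals = []
    for v in G:
        nbrs = list(G[v])
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if G.has_edge(a, b))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def oracle_betweenness(G):
    """Exhaustive enumeration of all shortest paths per pair."""
    nodes = sorted(G)
    n = len(nodes)
    score = dict.fromkeys(nodes, 0.0)

    def all_shortest_paths(s, t, dist):
        if s == t:
            return [[s]]
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in G[u]:
                if dist.get(v, -1) == dist[u] + 1 and dist.get(t, np.inf) >= dist[v]:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_distances(G, s)
        if t not in dist:
            continue
        paths = all_shortest_paths(s, t, dist)
        for p in paths:
            for v in p[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}


def oracle_information(G):
    comp = max(nx.connected_components(G), key=len)
    nodes = sorted(comp)
    idx = {v: i for i, v in enumerate(nodes)}
    L = nx.laplacian_matrix(G.subgraph(comp), nodelist=nodes).toarray()
    Linv = np.linalg.pinv(L.astype(float))
    out = {}
    for v in nodes:
        i = idx[v]
        r = sum(Linv[i, i] + Linv[j, j] - 2 * Linv[i, j]
                for j in range(len(nodes)) if j != i)
        out[v] = 1.0 / r
    return out


def single_linkage_groups(points, r):
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= r:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# Network dictionary -> graph
# ---------------------------------------------------------------------------

def simple_state():
    """Seed -> 10 unit steps -> terminal."""
    state = NetworkState()
    state.add_node("n:seed:0", [0, 0, 0], "seed")
    pts = [np.array([0.0, 0.0, float(i)]) for i in range(11)]
    state.add_edge("e:0:0", "n:seed:0", pts, cone="0000")
    state.add_node("n:0000:end", pts[-1], "terminal")
    state.close_edge("e:0:0", "n:0000:end")
    return state


class TestBuildGraph:
    def test_single_unbranched_cone(self):
        G = build_graph(simple_state())
        assert G.number_of_nodes() == 2
        assert G.number_of_edges() == 1
        (_, _, data), = G.edges(data=True)
        assert data["length"] == pytest.approx(10.0)

    def test_bifurcation_tree(self):
        state = NetworkState()
        state.add_node("n:seed:0", [0, 0, 0], "seed")
        state.add_node("n:b", [0, 0, 2], "bifurcation")
        state.add_edge("e:trunk", "n:seed:0",
                       [[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        state.close_edge("e:trunk", "n:b")
        for i, end in enumerate(([1, 0, 3], [-1, 0, 3])):
            state.add_node(f"n:t{i}", end, "terminal")
            state.add_edge(f"e:d{i}", "n:b", [[0, 0, 2], end])
            state.close_edge(f"e:d{i}", f"n:t{i}")
        G = build_graph(state)
        assert G.number_of_nodes() == 4
        assert G.number_of_edges() == 3
        assert nx.is_tree(nx.Graph(G))

    def test_dangling_endpoint_rejected(self):
        state = simple_state()
        del state.nodes["n:0000:end"]
        from ramify.network import NetworkIntegrityError
        with pytest.raises(NetworkIntegrityError):
            build_graph(state)

    def test_split_preserves_alias_resolution(self):
        state = simple_state()
        state.add_node("n:m", [0, 0, 4], "merge")
        k1, k2 = state.split_edge("e:0:0", 4, "n:m")
        resolved = {e.key for e in state.resolve_edge("e:0:0")}
        assert resolved == {k1, k2}
        G = build_graph(state)
        assert G.number_of_edges() == 2
        assert sum(d["length"] for _, _, d in G.edges(data=True)) == pytest.approx(10.0)

    def test_handshake(self):
        state = simple_state()
        G = build_graph(state)
        assert sum(dict(G.degree()).values()) == 2 * G.number_of_edges()


class TestMergeCloseNodes:
    def test_two_close_leaves_combined(self):
        G = nx.Graph()
        G.add_node("hub", position=(0, 0, 0))
        G.add_node("a", position=(5, 0, 0))
        G.add_node("b", position=(5, 0.5, 0))
        G.add_edge("hub", "a", length=5.0)
        G.add_edge("hub", "b", length=5.0)
        H = merge_close_nodes(G, 1.0)
        assert H.number_of_nodes() == 2
        assert H.number_of_edges() == 1

    def test_zero_resolution_identity(self):
        G = nx.Graph()
        G.add_node("a", position=(0, 0, 0))
        G.add_node("b", position=(0.1, 0, 0))
        G.add_edge("a", "b", length=0.1)
        H = merge_close_nodes(G, 0.0)
        assert set(H.nodes) == {"a", "b"}

    def test_matches_single_linkage_count(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, size=(40, 3))
        G = nx.Graph()
        for i, p in enumerate(pts):
            G.add_node(i, position=tuple(p))
        for i in range(39):
            G.add_edge(i, i + 1, length=1.0)
        for r in (0.5, 1.5, 3.0):
            H = merge_close_nodes(G, r)
            assert H.number_of_nodes() == single_linkage_groups(pts, r)

    def test_never_disconnects(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 8, size=(25, 3))
        G = nx.Graph()
        for i, p in enumerate(pts):
            G.add_node(i, position=tuple(p))
        for i in range(24):
            G.add_edge(i, i + 1, length=1.0)
        assert nx.is_connected(G)
        for r in (1.0, 2.0, 4.0):
            assert nx.is_connected(merge_close_nodes(G, r))


class TestTopologyMetrics:
    def test_triangle(self):
        G = nx.cycle_graph(3)
        rep = topology_metrics(G)
        assert rep.avg_degree == pytest.approx(2.0)
        assert rep.clustering == pytest.approx(1.0)
        assert rep.avg_shortest_path == pytest.approx(1.0)
        assert rep.density == pytest.approx(1.0)

    def test_path3(self):
        rep = topology_metrics(nx.path_graph(3))
        assert rep.clustering == 0.0
        assert rep.avg_shortest_path == pytest.approx(4.0 / 3.0)

    def test_star_betweenness(self):
        G = nx.star_graph(4)  # center 0, four leaves
        b = nx.betweenness_centrality(G, normalized=True)
        assert b[0] == pytest.approx(1.0)
        assert all(b[l] == 0.0 for l in range(1, 5))
        rep = topology_metrics(G)
        assert rep.betweenness == pytest.approx(1.0 / 5.0)

    def test_empty_graph_flagged(self):
        rep = topology_metrics(nx.Graph())
        assert rep.empty and rep.n_nodes == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_check_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        G = nx.gnm_random_graph(14, 24, seed=seed)
        rep = topology_metrics(G)
        assert rep.avg_shortest_path == pytest.approx(oracle_asp(G), abs=1e-9)
        assert rep.clustering == pytest.approx(oracle_clustering(G), abs=1e-9)
        bo = oracle_betweenness(G)
        assert rep.betweenness == pytest.approx(np.mean(list(bo.values())),
                                                abs=1e-9)
        io = oracle_information(G)
        assert rep.information == pytest.approx(np.mean(list(io.values())),
                                                abs=1e-9)
        comp_frac = len(max(nx.connected_components(G), key=len)) / 14
        assert rep.giant_fraction == pytest.approx(comp_frac)


class TestGiantComponentHistory:
    def test_isolated_and_connected_extremes(self):
        state = NetworkState()
        for c in range(4):
            state.add_node(f"n:seed:{c}", [c, 0, 0], "seed")
        assert giant_component_history([state], state.seed_node_keys()) == [0.25]
        # connect all seeds pairwise in a chain
        for c in range(3):
            state.add_edge(f"e:{c}", f"n:seed:{c}", [[c, 0, 0], [c + 1, 0, 0]])
            state.close_edge(f"e:{c}", f"n:seed:{c + 1}")
        assert giant_component_history([state], state.seed_node_keys()) == [1.0]

    def test_two_halves(self):
        state = NetworkState()
        for c in range(4):
            state.add_node(f"n:seed:{c}", [c, 0, 0], "seed")
        for a, b in ((0, 1), (2, 3)):
            state.add_edge(f"e:{a}", f"n:seed:{a}", [[a, 0, 0], [b, 0, 0]])
            state.close_edge(f"e:{a}", f"n:seed:{b}")
        assert giant_component_history([state], state.seed_node_keys()) == [0.5]


class TestExports:
    def test_graphml_round_trip(self, tmp_path):
        G = build_graph(simple_state())
        path = tmp_path / "net.graphml"
        save_graphml(G, path)
        H = load_graphml(path)
        assert set(H.nodes) == set(G.nodes)
        assert H.number_of_edges() == G.number_of_edges()
        for n in G.nodes:
            assert np.allclose(H.nodes[n]["position"],
                               G.nodes[n]["position"])

    def test_swc_round_trip(self, tmp_path):
        state = simple_state()
        files = export_swc(state, tmp_path)
        assert len(files) == 1
        rows = load_swc(files[0])
        assert rows.shape[0] == 11  # soma + 10 polyline samples
        assert rows[0, 1] == 1 and rows[0, 6] == -1
        assert np.allclose(rows[:, 4], np.arange(11.0))  # z coordinates
        # parent chain is consistent
        assert np.array_equal(rows[1:, 6], rows[:-1, 0])
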