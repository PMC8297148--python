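"""Global network measures against hand-enumerated and brute-force oracles."""

import math

import numpy as np
import pytest

from whpnet.metrics import (
    average_clustering,
    compute_all,
    degree_measures,
    density,
    distance_measures,
    triangle_count,
)
from whpnet.network import OneModeNetwork
from whpnet.participation import StakeholderGroup

from conftest import random_one_mode, to_networkx

GROUP = StakeholderGroup("company")


def complete_graph(n, weight=1):
    nodes = [f"n{i}" for i in range(n)]
    weights = {
        (nodes[i], nodes[j]): weight for i in range(n) for j in range(i + 1, n)
    }
    return OneModeNetwork({v: GROUP for v in nodes}, weights)


def graph_of(edges, extra_nodes=()):
    nodes = {n for e in edges for n in e} | set(extra_nodes)
    return OneModeNetwork(
        {v: GROUP for v in nodes},
        {tuple(sorted((u, v))): w for (u, v), w in edges.items()},
    )


def two_cliques_sharing_one_node():
    """Two 9-cliques overlapping in a single hub (17 nodes, 72 edges)."""
    a = [f"a{i}" for i in range(8)] + ["hub"]
    b = [f"b{i}" for i in range(8)] + ["hub"]
    weights = {}
    for clique in (a, b):
        for i in range(9):
            for j in range(i + 1, 9):
                weights[tuple(sorted((clique[i], clique[j])))] = 1
    return OneModeNetwork({v: GROUP for v in set(a) | set(b)}, weights)


def floyd_warshall(g):
    """Dense all-pairs hop distances (inf where unreachable)."""
    nodes = g.nodes
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.weights:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


class TestDegreeMeasures:
    def test_complete_nine_clique(self):
        assert degree_measures(complete_graph(9)) == (8.0, 8.0)

    def test_isolated_node(self):
        g = OneModeNetwork({"solo": GROUP}, {})
        assert degree_measures(g) == (0.0, 0.0)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            degree_measures(OneModeNetwork({}, {}))

    def test_matches_adjacency_sum_oracle(self, rng):
        for _ in range(50):
            g = random_one_mode(rng)
            deg = {n: 0 for n in g.node_groups}
            wdeg = {n: 0 for n in g.node_groups}
            for (u, v), w in g.weights.items():
                deg[u] += 1
                deg[v] += 1
                wdeg[u] += w
                wdeg[v] += w
            avg_d, avg_w = degree_measures(g)
            assert avg_d == pytest.approx(np.mean(list(deg.values())))
            assert avg_w == pytest.approx(np.mean(list(wdeg.values())))
            assert avg_w >= avg_d  # weights are >= 1


class TestDistanceMeasures:
    def test_complete_graph(self):
        assert distance_measures(complete_graph(9)) == (1, 1.0, True)

    def test_path_graph(self):
        g = graph_of({("a", "b"): 1, ("b", "c"): 1})
        diam, apl, connected = distance_measures(g)
        assert (diam, connected) == (2, True)
        assert apl == pytest.approx(4 / 3)

    def test_edgeless_graph_reports_missing(self):
        g = OneModeNetwork({"a": GROUP, "b": GROUP}, {})
        assert distance_measures(g) == (None, None, False)

    def test_disconnected_averages_over_reachable_pairs(self):
        g = graph_of({("a", "b"): 1, ("c", "d"): 1})
        diam, apl, connected = distance_measures(g)
        assert (diam, apl, connected) == (1, 1.0, False)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(50):
            g = random_one_mode(rng, max_nodes=25)
            if g.n_edges == 0:
                continue
            d = floyd_warshall(g)
            finite = d[np.triu_indices_from(d, k=1)]
            finite = finite[np.isfinite(finite)]
            diam, apl, connected = distance_measures(g)
            assert diam == int(finite.max())
            assert apl == pytest.approx(finite.mean())
            assert connected == bool(np.isfinite(d).all())


class TestDensity:
    def test_complete_and_sparse(self):
        assert density(complete_graph(9)) == pytest.approx(1.0)
        assert density(two_cliques_sharing_one_node()) == pytest.approx(72 / 136)

    def test_edgeless(self):
        assert density(OneModeNetwork({"a": GROUP, "b": GROUP}, {})) == 0.0

    def test_undefined_below_two_nodes(self):
        assert density(OneModeNetwork({"a": GROUP}, {})) is None


class TestTriangles:
    def test_complete_nine_clique(self):
        assert triangle_count(complete_graph(9)) == 84  # C(9,3)

    def test_tree_has_none(self):
        g = graph_of({("a", "b"): 1, ("b", "c"): 1, ("b", "d"): 1})
        assert triangle_count(g) == 0

    def test_matches_trace_oracle(self, rng):
        for _ in range(50):
            g = random_one_mode(rng)
            nodes = g.nodes
            idx = {v: i for i, v in enumerate(nodes)}
            a = np.zeros((len(nodes), len(nodes)))
            for u, v in g.weights:
                a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
            assert triangle_count(g) == round(np.trace(a @ a @ a) / 6)


class TestClustering:
    def test_complete_graph(self):
        assert average_clustering(complete_graph(9)) == pytest.approx(1.0)

    def test_star_is_zero(self):
        g = graph_of({("hub", f"leaf{i}"): 1 for i in range(4)})
        assert average_clustering(g) == 0.0

    def test_two_cliques_sharing_a_node(self):
        # hub: 56 of C(16,2)=120 neighbor pairs linked; 16 others fully clustered
        g = two_cliques_sharing_one_node()
        expected = (16 * 1.0 + 56 / 120) / 17
        assert average_clustering(g) == pytest.approx(expected)
        assert round(average_clustering(g), 3) == 0.969

    def test_exclude_low_degree_convention(self):
        g = graph_of({("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1,
                      ("c", "d"): 1}, extra_nodes=["iso"])
        incl = average_clustering(g)
        excl = average_clustering(g, exclude_low_degree=True)
        # d (deg 1) and iso (deg 0) count as zeros only in the inclusive mean
        assert incl == pytest.approx((1 + 1 + 1 / 3) / 5)
        assert excl == pytest.approx((1 + 1 + 1 / 3) / 3)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            average_clustering(OneModeNetwork({}, {}))


class TestComputeAll:
    def test_complete_nine_clique_row(self):
        m = compute_all(complete_graph(9))
        assert (m.n_nodes, m.n_edges) == (9, 36)
        assert (m.avg_degree, m.avg_weighted_degree) == (8.0, 8.0)
        assert (m.diameter, m.avg_path_length) == (1, 1.0)
        assert m.density == pytest.approx(1.0)
        assert m.n_triangles == 84
        assert m.avg_clustering == pytest.approx(1.0)
        assert m.is_connected

    def test_single_weighted_edge(self):
        g = graph_of({("a", "b"): 3})
        m = compute_all(g)
        assert (m.n_nodes, m.n_edges, m.avg_degree, m.avg_weighted_degree) \
            == (2, 1, 1.0, 3.0)
        assert (m.diameter, m.avg_path_length, m.density) == (1, 1.0, 1.0)
        assert (m.n_triangles, m.avg_clustering) == (0, 0.0)

    def test_empty_graph_gives_missing_fields(self):
        m = compute_all(OneModeNetwork({}, {}))
        assert (m.n_nodes, m.n_edges, m.n_triangles) == (0, 0, 0)
        assert m.avg_degree is None and m.density is None

    def test_fields_match_component_operations(self, rng):
        for _ in range(20):
            g = random_one_mode(rng)
            m = compute_all(g)
            assert (m.avg_degree, m.avg_weighted_degree) == degree_measures(g)
            assert (m.diameter, m.avg_path_length, m.is_connected) \
                == distance_measures(g)
            assert m.density == density(g)
            assert m.n_triangles == triangle_count(g)
            if m.avg_clustering is not None:
                assert m.avg_clustering == average_clustering(g)

    def test_rounded_rendering(self):
        m = compute_all(two_cliques_sharing_one_node())
        r = m.rounded()
        assert r["avg_degree"] == 8.5
        assert r["density"] == 0.529
        assert r["avg_clustering"] == 0.969
        edgeless = compute_all(OneModeNetwork({"a": GROUP, "b": GROUP}, {}))
        assert edgeless.rounded()["diameter"] == "NA"
        assert edgeless.rounded()["avg_path_length"] == "NA"


class TestInvariantsAndNetworkxOracle:
    def test_invariants_on_random_graphs(self, rng):
        for _ in range(50):
            g = random_one_mode(rng)
            if g.n_nodes == 0:
                continue
            m = compute_all(g)
            assert m.avg_degree * g.n_nodes == pytest.approx(2 * g.n_edges)
            assert m.avg_weighted_degree * g.n_nodes == pytest.approx(
                2 * sum(g.weights.values()))
            if m.density is not None:
                assert 0 <= m.density <= 1
            assert 0 <= m.avg_clustering <= 1
            if m.diameter is not None:
                assert m.diameter >= m.avg_path_length >= 1

    def test_agrees_with_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        checked = 0
        while checked < 60:
            g = random_one_mode(rng, max_nodes=25)
            if g.n_nodes < 2:
                continue
            checked += 1
            G = to_networkx(g)
            m = compute_all(g)
            assert m.density == pytest.approx(nx.density(G))
            assert m.n_triangles == sum(nx.triangles(G).values()) // 3
            assert m.avg_clustering == pytest.approx(
                nx.average_clustering(G, count_zeros=True))
            if nx.is_connected(G) and g.n_edges:
                assert m.diameter == nx.diameter(G)
                assert m.avg_path_length == pytest.approx(
                    nx.average_shortest_path_length(G))
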