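"""Graph metrics against hand arithmetic and brute-force oracles."""

import itertools

import numpy as np
import pytest

from fcgraph.metrics import (
    closeness_centrality,
    clustering_coefficient,
    degree_features,
    feature_vector,
    is_connected,
    modularity,
    modularity_value,
    rich_club_subgraph,
    shortest_paths,
    threshold_graph,
)
from tests.conftest import make_graph, random_graph


def brute_force_shortest_paths(weights, directed):
    """Exhaustive enumeration of simple paths with 1/w edge costs."""
    n = len(weights)
    with np.errstate(divide="ignore"):
        cost = np.where(weights > 0, 1.0 / weights, np.inf)
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def visit(node, target, seen, acc):
        if acc >= best[seen[0], target]:
            return
        if node == target:
            best[seen[0], target] = acc
            return
        for nxt in range(n):
            if nxt not in seen and np.isfinite(cost[node, nxt]):
                visit(nxt, target, seen + [nxt], acc + cost[node, nxt])

    for s in range(n):
        for t in range(n):
            if s != t:
                visit(s, t, [s], 0.0)
    if not directed:
        best = np.minimum(best, best.T)
    return best


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1 :]
        yield [[first]] + partition


def exhaustive_best_modularity(weights):
    n = len(weights)
    best = -np.inf
    for partition in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(partition):
            labels[block] = c
        best = max(best, modularity_value(weights, labels))
    return best


class TestThreshold:
    def test_values_below_threshold_zeroed(self, graph_factory):
        w = np.array([[0, 0.05, 0.3], [0.05, 0, 0.7], [0.3, 0.7, 0]])
        g = threshold_graph(graph_factory(w), 0.1)
        assert set(np.unique(g.weights)) == {0.0, 0.3, 0.7}

    def test_zero_threshold_is_identity(self, graph_factory):
        g = random_graph(np.random.default_rng(0), 6)
        assert np.array_equal(threshold_graph(g, 0.0).weights, g.weights)

    def test_threshold_above_max_empties_graph(self, graph_factory):
        g = random_graph(np.random.default_rng(1), 5)
        assert threshold_graph(g, 1.01).weights.sum() == 0

    def test_idempotent_and_monotone(self):
        g = random_graph(np.random.default_rng(2), 7)
        g1 = threshold_graph(g, 0.4)
        assert np.array_equal(threshold_graph(g1, 0.4).weights, g1.weights)
        e_low = threshold_graph(g, 0.2).weights > 0
        e_high = threshold_graph(g, 0.6).weights > 0
        assert np.all(e_low | ~e_high)  # high-threshold edges survive low


class TestConnected:
    def test_complete_graph_connected(self):
        w = np.ones((4, 4)) - np.eye(4)
        assert is_connected(make_graph(w))

    def test_isolated_node_disconnects(self):
        w = np.ones((4, 4)) - np.eye(4)
        w[3, :] = w[:, 3] = 0
        assert not is_connected(make_graph(w))

    def test_single_bridge_keeps_connection(self):
        w = np.zeros((6, 6))
        for i, j in ((0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)):
            w[i, j] = w[j, i] = 0.5
        assert not is_connected(make_graph(w))
        w[2, 3] = w[3, 2] = 0.1
        assert is_connected(make_graph(w))


class TestRichClub:
    def test_keeps_ceil_fraction(self):
        g = random_graph(np.random.default_rng(0), 20)
        assert rich_club_subgraph(g, 0.1).n_nodes == 2

    def test_star_hub_always_included(self):
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = 0.9
        rich = rich_club_subgraph(make_graph(w), 0.4)
        assert 1 in rich.node_ids  # node ids are 1-based; hub is node 1

    def test_ties_broken_by_lowest_id(self):
        w = np.ones((10, 10)) - np.eye(10)
        rich = rich_club_subgraph(make_graph(w), 0.3)
        assert rich.node_ids == [1, 2, 3]

    def test_tiny_result_rejected(self):
        g = random_graph(np.random.default_rng(1), 5)
        with pytest.raises(ValueError):
            rich_club_subgraph(g, 0.1)


class TestDegree:
    def test_uniform_weights_give_unit_deg_n(self):
        w = 0.3 * (np.ones((5, 5)) - np.eye(5))
        _, deg_n = degree_features(make_graph(w))
        assert np.allclose(deg_n, 1.0)

    def test_hand_arithmetic(self):
        # node 1 weights {0.2, 0.8}: deg_w = 1.0, deg_n = 1/(2 * 0.8) = 0.625
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.8
        deg_w, deg_n = degree_features(make_graph(w))
        assert deg_w[0] == pytest.approx(1.0)
        assert deg_n[0] == pytest.approx(0.625)

    def test_deg_n_bounded(self):
        for seed in range(5):
            g = random_graph(np.random.default_rng(seed), 8)
            _, deg_n = degree_features(g)
            assert np.all((deg_n >= 0) & (deg_n <= 1 + 1e-12))

    def test_isolated_node_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        _, deg_n = degree_features(make_graph(w))
        assert deg_n[2] == 0.0


class TestShortestPaths:
    def test_chain_distance(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        dist = shortest_paths(make_graph(w))
        assert dist[0, 2] == pytest.approx(4.0)  # 1/0.5 + 1/0.5

    def test_strong_two_hop_beats_weak_direct(self):
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 0.2  # direct cost 5
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5  # two-hop cost 4
        dist = shortest_paths(make_graph(w))
        assert dist[0, 2] == pytest.approx(4.0)

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_enumeration_oracle(self, directed):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            g = random_graph(rng, n, density=0.5, directed=directed)
            assert np.allclose(
                shortest_paths(g), brute_force_shortest_paths(g.weights, directed)
            )


class TestCloseness:
    def test_uniform_triangle(self):
        w = 0.5 * (np.ones((3, 3)) - np.eye(3))
        assert np.allclose(closeness_centrality(make_graph(w)), 0.5)

    def test_scaling_homogeneity(self):
        g = random_graph(np.random.default_rng(0), 6)
        base = closeness_centrality(g)
        scaled = closeness_centrality(make_graph(3.0 * g.weights))
        assert np.allclose(scaled, 3.0 * base)

    def test_permutation_invariance(self):
        g = random_graph(np.random.default_rng(1), 6)
        perm = np.random.default_rng(2).permutation(6)
        gp = make_graph(g.weights[np.ix_(perm, perm)])
        assert np.allclose(closeness_centrality(gp), closeness_centrality(g)[perm])

    def test_disconnected_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(ValueError):
            closeness_centrality(make_graph(w))


class TestClusteringCoefficient:
    def test_binary_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(clustering_coefficient(make_graph(w)), 1.0)

    def test_path_centre_has_no_triangle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert clustering_coefficient(make_graph(w))[1] == 0.0

    def test_matches_binary_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 10
            a = (rng.random((n, n)) < 0.4).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            cc = clustering_coefficient(make_graph(a))
            for v in range(n):
                neigh = np.nonzero(a[v])[0]
                k = len(neigh)
                if k < 2:
                    assert cc[v] == 0.0
                    continue
                triangles = sum(
                    a[i, j] for i, j in itertools.combinations(neigh, 2)
                )
                assert cc[v] == pytest.approx(2 * triangles / (k * (k - 1)))


class TestModularity:
    def test_single_community_q_is_zero(self):
        g = random_graph(np.random.default_rng(0), 6)
        assert modularity_value(g.weights, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_two_triangles_optimum(self):
        w = np.zeros((6, 6))
        for i, j in ((0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)):
            w[i, j] = w[j, i] = 1.0
        q, labels = modularity(make_graph(w))
        assert q == pytest.approx(0.5)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert exhaustive_best_modularity(w) == pytest.approx(0.5)

    def test_louvain_matches_exhaustive_on_small_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            g = random_graph(rng, 6, density=0.5)
            if g.weights.sum() == 0:
                continue
            q, _ = modularity(g)
            assert q >= exhaustive_best_modularity(g.weights) - 1e-9

    def test_q_evaluated_exactly_on_returned_partition(self):
        g = random_graph(np.random.default_rng(2), 8)
        q, labels = modularity(g)
        assert q == pytest.approx(modularity_value(g.weights, labels), abs=1e-12)
        singleton = modularity_value(g.weights, np.arange(8))
        assert q >= singleton - 1e-12

    def test_directed_rejected(self):
        g = random_graph(np.random.default_rng(3), 5, directed=True)
        with pytest.raises(ValueError):
            modularity(g)


class TestFeatureVector:
    def test_dimension_undirected_vs_directed(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 8, density=1.0)
        assert feature_vector(g).d == 22
        gd = random_graph(rng, 8, density=1.0, directed=True)
        assert feature_vector(gd).d == 21

    def test_degenerate_distribution_moment_convention(self):
        w = 0.4 * (np.ones((5, 5)) - np.eye(5))
        fv = feature_vector(make_graph(w))
        vals = dict(zip(fv.names, fv.values))
        assert vals["weight_mean"] == pytest.approx(0.4)
        assert vals["weight_std"] == 0.0
        assert vals["weight_skew"] == 0.0
        assert vals["weight_kurt"] == 0.0
        assert vals["n_nodes_over_100"] == pytest.approx(0.05)

    def test_relabeling_invariance(self):
        g = random_graph(np.random.default_rng(1), 7, density=1.0)
        perm = np.random.default_rng(2).permutation(7)
        gp = make_graph(g.weights[np.ix_(perm, perm)])
        assert np.allclose(feature_vector(gp).values, feature_vector(g).values)

    def test_disconnected_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.raises(ValueError):
            feature_vector(make_graph(w))
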