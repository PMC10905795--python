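"""Weighted network statistics against brute-force and binary oracles."""

import itertools

import numpy as np
import pytest

from eegnetvar import (
    WeightedGraph,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    network_metrics,
    shortest_paths,
)


# ---------------------------------------------------------------- oracles

def enumerate_shortest(weights):
    """All-pairs shortest paths by exhaustive simple-path enumeration.

    Returns (distance matrix, dict (i,j) -> list of minimal-length paths).
    Only feasible for n <= 6.
    """
    n = weights.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    nodes = range(n)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths = {}
    for i, j in itertools.permutations(nodes, 2):
        best, best_paths = np.inf, []
        others = [k for k in nodes if k not in (i, j)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (i, *mid, j)
                total = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                if not np.isfinite(total):
                    continue
                if total < best - 1e-12:
                    best, best_paths = total, [path]
                elif abs(total - best) <= 1e-12:
                    best_paths.append(path)
        dist[i, j] = best
        paths[(i, j)] = best_paths
    return dist, paths


def brute_force_bc(weights):
    n = weights.shape[0]
    _, paths = enumerate_shortest(weights)
    bc = np.zeros(n)
    for (h, j), plist in paths.items():
        sigma = len(plist)
        if sigma == 0:  # unreachable pair
            continue
        for i in range(n):
            if i in (h, j):
                continue
            through = sum(1 for p in plist if i in p[1:-1])
            bc[i] += through / sigma
    return bc / ((n - 1) * (n - 2))


def brute_force_cc(weights):
    n = weights.shape[0]
    wn = weights / weights.max()
    ci = np.zeros(n)
    for i in range(n):
        k = int((weights[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j, h in itertools.permutations(range(n), 2):
            if j == i or h == i:
                continue
            t += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1 / 3)
        ci[i] = t / (k * (k - 1))
    return ci.mean(), ci


def random_connected_weights(rng, n):
    w = np.zeros((n, n))
    # random ring guarantees connectivity, then sprinkle extra edges
    order = rng.permutation(n)
    for a, b in zip(order, np.roll(order, 1)):
        w[a, b] = w[b, a] = rng.uniform(0.2, 1.0)
    for i, j in itertools.combinations(range(n), 2):
        if w[i, j] == 0 and rng.random() < 0.4:
            w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
    return w


# ----------------------------------------------------------------- tests

class TestShortestPaths:
    def test_complete_unit_graph(self):
        w = 1.0 - np.eye(4)
        d = shortest_paths(w)
        assert np.allclose(d, 1.0 - np.eye(4))

    def test_chain_with_reciprocal_lengths(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        d = shortest_paths(w)
        assert d[0, 2] == pytest.approx(4.0)

    def test_agrees_with_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            w = random_connected_weights(rng, n)
            d_fast = shortest_paths(w)
            d_slow, _ = enumerate_shortest(w)
            assert np.allclose(d_fast, d_slow, atol=1e-10)


class TestCharacteristicPathLength:
    def test_complete_unit_graph_is_one(self):
        for n in (3, 5, 8):
            assert characteristic_path_length(1.0 - np.eye(n)) == pytest.approx(1.0)

    def test_three_node_chain(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        assert characteristic_path_length(w) == pytest.approx(8 / 3)

    def test_edge_addition_never_increases(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 8))
            w = random_connected_weights(rng, n)
            before = characteristic_path_length(w)
            empty = [(i, j) for i, j in itertools.combinations(range(n), 2)
                     if w[i, j] == 0]
            if not empty:
                continue
            i, j = empty[int(rng.integers(len(empty)))]
            w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
            assert characteristic_path_length(w) <= before + 1e-12

    def test_fully_disconnected_errors(self):
        with pytest.raises(ValueError):
            characteristic_path_length(np.zeros((4, 4)))


class TestClustering:
    def test_binary_triangle(self):
        w = 1.0 - np.eye(3)
        cc, ci = clustering_coefficient(w)
        assert cc == pytest.approx(1.0)
        assert ci == pytest.approx([1.0, 1.0, 1.0])

    def test_path_endpoint_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        _, ci = clustering_coefficient(w)
        assert ci[0] == 0.0 and ci[2] == 0.0

    def test_weighted_triangle_geometric_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.25
        _, ci = clustering_coefficient(w)
        expected = (1.0 * 0.5 * 0.25) ** (1 / 3)
        assert ci == pytest.approx([expected] * 3)

    def test_binary_reduction_matches_triangle_count(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            w = (rng.random((n, n)) < 0.5).astype(float)
            w = np.triu(w, 1)
            w = w + w.T
            if w.max() == 0:
                continue
            cc, ci = clustering_coefficient(w)
            import networkx as nx

            G = nx.from_numpy_array(w)
            expected = nx.clustering(G)
            assert ci == pytest.approx([expected[i] for i in range(n)], abs=1e-12)


class TestBetweenness:
    def test_star_center(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        bc = betweenness_centrality(w)
        assert bc[0] == pytest.approx(1.0)
        assert bc[1:] == pytest.approx(np.zeros(4))

    def test_chain_middle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        bc = betweenness_centrality(w)
        assert bc == pytest.approx([0.0, 1.0, 0.0])

    def test_complete_graph_zero(self):
        bc = betweenness_centrality(1.0 - np.eye(6))
        assert bc == pytest.approx(np.zeros(6))

    def test_fractional_ties_match_enumeration(self):
        # weights from a small set so multiple exactly-tied shortest paths occur
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 7))
            w = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.7:
                    w[i, j] = w[j, i] = rng.choice([0.25, 0.5, 1.0])
            if not np.isfinite(shortest_paths(w)).all():
                continue
            assert betweenness_centrality(w) == pytest.approx(
                brute_force_bc(w), abs=1e-10)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            betweenness_centrality(np.zeros((2, 2)))


class TestScaleBehavior:
    def test_uniform_scaling(self):
        rng = np.random.default_rng(14)
        w = random_connected_weights(rng, 6)
        c = 3.7
        assert characteristic_path_length(c * w) == pytest.approx(
            characteristic_path_length(w) / c)
        assert betweenness_centrality(c * w) == pytest.approx(
            betweenness_centrality(w), abs=1e-12)
        assert clustering_coefficient(c * w)[0] == pytest.approx(
            clustering_coefficient(w)[0])


class TestNetworkMetricsBundle:
    def test_uniform_matrix_closed_form(self):
        w = np.full((30, 30), 0.1)
        np.fill_diagonal(w, 0.0)
        m = network_metrics(w)
        assert m.cpl == pytest.approx(10.0)
        assert m.cc == pytest.approx(1.0)
        assert m.bc == pytest.approx(np.zeros(30), abs=1e-12)

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            network_metrics(np.zeros((5, 5)))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(15)
        w = random_connected_weights(rng, 6)
        m = network_metrics(w)
        perm = rng.permutation(6)
        mp = network_metrics(w[np.ix_(perm, perm)])
        assert mp.cpl == pytest.approx(m.cpl)
        assert mp.cc == pytest.approx(m.cc)
        assert mp.bc == pytest.approx(m.bc[perm], abs=1e-10)

    def test_epoch_scope_rejected(self):
        from eegnetvar import ConnectivityMatrix

        cm = ConnectivityMatrix(np.array([[0, 0.5], [0.5, 0]]), ("a", "b"),
                                scope="epoch")
        with pytest.raises(ValueError):
            network_metrics(cm)

    def test_brute_force_equivalence_all_metrics(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            n = int(rng.integers(4, 7))
            w = random_connected_weights(rng, n)
            m = network_metrics(w)
            d_slow, _ = enumerate_shortest(w)
            off = d_slow[~np.eye(n, dtype=bool)]
            assert m.cpl == pytest.approx(off[np.isfinite(off)].mean(), abs=1e-10)
            cc_slow, ci_slow = brute_force_cc(w)
            assert m.cc == pytest.approx(cc_slow, abs=1e-10)
            assert m.bc == pytest.approx(brute_force_bc(w), abs=1e-10)
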