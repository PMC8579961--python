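import numpy as np
import pytest

import phaselink as pl
from phaselink.graph import (
    ThresholdedGraph,
    clustering_coefficients,
    global_efficiency,
    local_efficiency,
    node_degrees,
    normalized_metrics,
    path_length,
    proportional_threshold,
    random_surrogates,
)

INF = np.inf


# ---------------------------------------------------------------- oracles
def floyd_warshall_lengths(W):
    """All-pairs shortest 1/W lengths by triple loop."""
    n = W.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                d[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_oracle(W):
    """Literal triple-loop evaluation of the triple-product clustering."""
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for k in range(n):
            for l in range(n):
                if k != i and l != i and l != k:
                    num += W[i, k] * W[i, l] * W[k, l]
                    den += W[i, k] * W[i, l]
        C[i] = num / den if den > 0 else 0.0
    return C


def local_efficiency_oracle(W):
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        d = floyd_warshall_lengths(sub)
        acc = 0.0
        for aj, j in enumerate(nbrs):
            for ah, h in enumerate(nbrs):
                if j != h and np.isfinite(d[aj, ah]):
                    acc += (W[i, j] * W[i, h] / d[aj, ah]) ** (1 / 3)
        total += acc / (k * (k - 1))
    return total / (2 * n)


def path_length_oracle(W):
    d = floyd_warshall_lengths(W)
    vals = [d[i, j] for i in range(len(W)) for j in range(len(W))
            if i != j and np.isfinite(d[i, j])]
    return np.mean(vals)


def global_efficiency_oracle(W):
    n = len(W)
    d = floyd_warshall_lengths(W)
    acc = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return acc / (n * (n - 1))


def random_weighted_graph(rng, n, density=0.6):
    A = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < density)
    W = np.triu(A, 1)
    W = W + W.T
    return W


# ----------------------------------------------------------- thresholding
class TestProportionalThreshold:
    def test_60_nodes_10_percent_keeps_177_edges(self, rng):
        W = random_weighted_graph(rng, 60, density=1.0)
        G = proportional_threshold(W, 0.10)
        assert G.n_retained == 177  # round(0.10 * 1770)
        assert np.count_nonzero(np.triu(G.W, 1)) == 177

    def test_full_proportion_is_identity(self, rng):
        W = random_weighted_graph(rng, 8, density=1.0)
        G = proportional_threshold(W, 1.0)
        np.testing.assert_array_equal(G.W, W)

    def test_five_nodes_keeps_single_largest(self, rng):
        W = random_weighted_graph(rng, 5, density=1.0)
        G = proportional_threshold(W, 0.10)
        iu = np.triu_indices(5, 1)
        assert G.n_retained == 1
        assert G.W.max() == W[iu].max()

    def test_retained_weights_dominate_discarded(self, rng):
        W = random_weighted_graph(rng, 12, density=1.0)
        G = proportional_threshold(W, 0.3)
        kept = G.W[np.triu_indices(12, 1)]
        dropped = W[np.triu_indices(12, 1)][kept == 0]
        assert kept[kept > 0].min() >= dropped.max()

    def test_negative_weights_zeroed_first(self):
        W = np.array([[0, -0.9, 0.1], [-0.9, 0, 0.2], [0.1, 0.2, 0]], dtype=float)
        G = proportional_threshold(W, 2 / 3)
        assert G.W[0, 1] == 0.0 and G.W[0, 2] == 0.1 and G.W[1, 2] == 0.2

    def test_tie_break_is_lexicographic_and_deterministic(self):
        W = np.ones((4, 4)) - np.eye(4)
        G1 = proportional_threshold(W, 0.5)  # round(3) of 6 equal edges
        G2 = proportional_threshold(W, 0.5)
        np.testing.assert_array_equal(G1.W, G2.W)
        assert G1.W[0, 1] == 1 and G1.W[0, 2] == 1 and G1.W[0, 3] == 1

    def test_monotone_in_proportion(self, rng):
        W = random_weighted_graph(rng, 10, density=1.0)
        counts = [proportional_threshold(W, p).n_retained
                  for p in (0.1, 0.3, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts)


class TestSimpleMetrics:
    def test_degrees_complete_constant(self):
        n, w = 6, 0.4
        W = np.full((n, n), w) - w * np.eye(n)
        K, K_mean = node_degrees(ThresholdedGraph(W, 1.0, 15))
        np.testing.assert_allclose(K, (n - 1) * w)
        assert K_mean == pytest.approx((n - 1) * w)

    def test_degrees_hand_example(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = 0.3
        K, _ = node_degrees(ThresholdedGraph(W, 1.0, 2))
        np.testing.assert_allclose(K, [0.5, 0.2, 0.3])

    def test_triangle_clustering_equals_weight(self):
        w = 0.7
        W = np.full((3, 3), w) - w * np.eye(3)
        C, C_mean = clustering_coefficients(ThresholdedGraph(W, 1.0, 3))
        np.testing.assert_allclose(C, w)
        assert C_mean == pytest.approx(w)

    def test_path_middle_node_has_zero_clustering(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        C, _ = clustering_coefficients(ThresholdedGraph(W, 1.0, 2))
        assert C[1] == 0.0

    def test_chain_path_length_and_efficiency(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        G = ThresholdedGraph(W, 1.0, 2)
        assert path_length(G) == pytest.approx(4 / 3)  # d in {1, 1, 2}
        assert global_efficiency(G) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_complete_unit_graph(self):
        W = np.ones((5, 5)) - np.eye(5)
        G = ThresholdedGraph(W, 1.0, 10)
        assert path_length(G) == pytest.approx(1.0)
        assert global_efficiency(G) == pytest.approx(1.0)

    def test_disconnected_pairs_excluded_from_path_length(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        assert path_length(ThresholdedGraph(W, 1.0, 2)) == pytest.approx(1.0)

    def test_empty_graph_degenerate(self):
        G = ThresholdedGraph(np.zeros((4, 4)), 1.0, 0)
        assert node_degrees(G)[1] == 0.0
        assert global_efficiency(G) == 0.0
        with pytest.raises(ValueError, match="no edges"):
            path_length(G)

    def test_low_degree_nodes_give_zero_local_efficiency(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.8
        assert local_efficiency(ThresholdedGraph(W, 1.0, 1)) == 0.0


class TestOracleEquivalence:
    def test_200_random_graphs_match_brute_force(self, rng):
        for trial in range(200):
            n = int(rng.integers(3, 9))
            W = random_weighted_graph(rng, n)
            if not np.any(W > 0):
                continue
            G = ThresholdedGraph(W, 1.0, int(np.count_nonzero(np.triu(W, 1))))
            C, _ = clustering_coefficients(G)
            np.testing.assert_allclose(C, clustering_oracle(W), atol=1e-10)
            assert local_efficiency(G) == pytest.approx(
                local_efficiency_oracle(W), abs=1e-10
            )
            assert global_efficiency(G) == pytest.approx(
                global_efficiency_oracle(W), abs=1e-10
            )
            d = floyd_warshall_lengths(W)
            if np.isfinite(d[~np.eye(n, dtype=bool)]).any():
                assert path_length(G) == pytest.approx(
                    path_length_oracle(W), abs=1e-10
                )

    def test_complete_unit_4_node_local_efficiency(self):
        W = np.ones((4, 4)) - np.eye(4)
        G = ThresholdedGraph(W, 1.0, 6)
        assert local_efficiency(G) == pytest.approx(
            local_efficiency_oracle(W), abs=1e-12
        )

    def test_scale_behaviour(self, rng):
        W = random_weighted_graph(rng, 7)
        c = 3.7
        G1 = ThresholdedGraph(W, 1.0, 0)
        G2 = ThresholdedGraph(c * W, 1.0, 0)
        assert node_degrees(G2)[1] == pytest.approx(c * node_degrees(G1)[1])
        assert clustering_coefficients(G2)[1] == pytest.approx(
            c * clustering_coefficients(G1)[1]
        )
        assert global_efficiency(G2) == pytest.approx(c * global_efficiency(G1))
        assert path_length(G2) == pytest.approx(path_length(G1) / c)


class TestSurrogates:
    def test_weight_multiset_and_total_conserved(self, rng):
        W = random_weighted_graph(rng, 10)
        G = ThresholdedGraph(W, 1.0, 0)
        (s,) = random_surrogates(G, 1, seed=7)
        iu = np.triu_indices(10, 1)
        np.testing.assert_allclose(np.sort(s.W[iu]), np.sort(W[iu]))
        assert s.W.sum() == pytest.approx(W.sum())
        np.testing.assert_allclose(s.W, s.W.T)
        assert np.all(np.diag(s.W) == 0)

    def test_same_seed_reproduces_sequence(self, rng):
        W = random_weighted_graph(rng, 8)
        G = ThresholdedGraph(W, 1.0, 0)
        a = random_surrogates(G, 5, seed=3)
        b = random_surrogates(G, 5, seed=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.W, sb.W)


class TestNormalizedMetrics:
    def test_self_normalisation_is_unity(self, rng):
        W = random_weighted_graph(rng, 8)
        G = ThresholdedGraph(W, 1.0, 0)
        gamma, lam, sigma = normalized_metrics(G, [G])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_sigma_identity(self, rng):
        W = random_weighted_graph(rng, 12)
        G = ThresholdedGraph(W, 1.0, 0)
        gamma, lam, sigma = normalized_metrics(G, random_surrogates(G, 10, seed=1))
        assert sigma == pytest.approx(gamma / lam, rel=1e-12)

    def test_ring_lattice_is_more_clustered_than_reshuffles(self):
        # strong near-neighbour weights, weak long-range: gamma > 1
        n = 20
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ring = min(abs(i - j), n - abs(i - j))
                W[i, j] = W[j, i] = 1.0 if ring <= 2 else 0.05
        G = ThresholdedGraph(W, 1.0, 0)
        gamma, _, _ = normalized_metrics(G, random_surrogates(G, 50, seed=11))
        assert gamma > 1.0


class TestGraphMetricsRecord:
    def test_record_consistency(self, rng):
        W = random_weighted_graph(rng, 16, density=1.0)
        cm = pl.ConnectivityMatrix(W, tuple(f"c{i}" for i in range(16)), "dwpli",
                                   pl.DEFAULT_BANDS[1])
        rec = pl.graph_metrics_record(cm, p=0.4, n_surrogates=10, seed=5)
        assert rec.sigma == pytest.approx(rec.clustering_norm / rec.path_length_norm)
        assert rec.mean_connectivity == pytest.approx(cm.global_mean())
        assert rec.global_efficiency > 0
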