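import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch

from interclust.datatypes import NeighborGraph, SimilarityMatrix
from interclust.graph import (
    agglomerate_subpartitions,
    build_knn_graph,
    chameleon_cluster,
    partition_graph,
)
from interclust.graph import _best_bisection

from conftest import random_similarity


def _sim(values):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(
        sample_ids=[str(i) for i in range(values.shape[0])], values=values
    )


def exhaustive_min_cut(W: np.ndarray, balance: float = 0.10) -> float:
    """Minimum cut weight over all balance-feasible bipartitions."""
    n = W.shape[0]
    floor = max(1, int(np.ceil(balance * n)))
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        mask = np.array((1,) + bits, dtype=bool)
        sa = mask.sum()
        if not (floor <= sa <= n - floor):
            continue
        cut = W[np.ix_(mask, ~mask)].sum()
        best = min(best, cut)
    return best


def random_sparse_graph(rng, n) -> np.ndarray:
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = rng.choice([j for j in range(n) if j != i],
                          size=min(3, n - 1), replace=False)
        for j in nbrs:
            W[i, j] = W[j, i] = max(W[i, j], rng.uniform(0.05, 1.0))
    return W


class TestKnnGraph:
    def test_full_k_gives_complete_graph(self, small_sim):
        g = build_knn_graph(small_sim, small_sim.n_samples - 1)
        n = g.n_vertices
        assert (g.weights > 0).sum() == n * (n - 1)

    def test_union_symmetrization_three_samples(self):
        s = _sim([[1, 0.9, 0.2], [0.9, 1, 0.8], [0.2, 0.8, 1]])
        g = build_knn_graph(s, 1)
        assert [(i, j) for i, j, _ in g.edges()] == [(0, 1), (1, 2)]
        assert g.weights[0, 1] == 0.9

    def test_matches_row_sort_oracle(self, rng):
        s = random_similarity(12, rng)
        k = 3
        g = build_knn_graph(s, k)
        expected = np.zeros((12, 12), dtype=bool)
        for i in range(12):
            order = sorted((j for j in range(12) if j != i),
                           key=lambda j: -s.values[i, j])
            kth_sim = s.values[i, order[k - 1]]
            for j in order:
                if s.values[i, j] >= kth_sim:  # ties at rank k included
                    expected[i, j] = True
        expected |= expected.T
        assert np.array_equal(g.weights > 0, expected)

    def test_degree_floor(self, rng):
        s = random_similarity(15, rng)
        g = build_knn_graph(s, 4)
        assert g.degree().min() >= 4

    @pytest.mark.parametrize("k", [0, 15])
    def test_k_out_of_range(self, small_sim, k):
        with pytest.raises(ValueError):
            build_knn_graph(small_sim, k)


class TestPartition:
    def test_two_components_zero_cut(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            W[i, j] = W[j, i] = 0.9
        g = NeighborGraph(n_vertices=6, weights=W, k_neighbors=1)
        labels = partition_graph(g, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_a_equals_one_is_identity(self, small_sim):
        g = build_knn_graph(small_sim, 3)
        assert len(np.unique(partition_graph(g, 1))) == 1

    def test_exactly_a_nonempty_parts(self, rng):
        s = random_similarity(20, rng)
        g = build_knn_graph(s, 4)
        for a in (2, 5, 9):
            labels = partition_graph(g, a)
            assert len(np.unique(labels)) == a

    @pytest.mark.parametrize("a", [0, 99])
    def test_a_out_of_range(self, small_sim, a):
        g = build_knn_graph(small_sim, 3)
        with pytest.raises(ValueError):
            partition_graph(g, a)

    def test_bisection_matches_exhaustive_oracle(self, rng):
        """Heuristic cut equals the enumerated optimum on small graphs."""
        optimal, trials = 0, 30
        for _ in range(trials):
            n = int(rng.integers(6, 13))
            W = random_sparse_graph(rng, n)
            _, cut, _ = _best_bisection(W, 0.10)
            best = exhaustive_min_cut(W)
            assert cut <= 1.05 * best + 1e-12
            optimal += abs(cut - best) < 1e-9
        assert optimal >= int(0.9 * trials)

    def test_deterministic(self, rng):
        s = random_similarity(30, rng)
        g = build_knn_graph(s, 5)
        l1 = partition_graph(g, 5, seed=7)
        l2 = partition_graph(g, 5, seed=7)
        assert np.array_equal(l1, l2)


class TestAgglomerate:
    def _complete_graph(self, sim):
        return build_knn_graph(sim, sim.n_samples - 1)

    def test_k_equals_current_unchanged(self, small_sim):
        g = self._complete_graph(small_sim)
        labels = np.arange(10) % 4
        out = agglomerate_subpartitions(g, labels, 4, linkage="single")
        # same partition up to relabeling
        assert len(np.unique(out)) == 4
        for c in range(4):
            assert len(np.unique(out[labels == c])) == 1

    @pytest.mark.parametrize("linkage,scipy_method", [("single", "single"),
                                                      ("complete", "complete")])
    def test_matches_textbook_linkage(self, rng, linkage, scipy_method):
        """Singleton start on a complete graph reproduces the classic
        agglomeration on d = 1 - s, checked against scipy at every cut."""
        s = random_similarity(10, rng)
        g = self._complete_graph(s)
        d = 1.0 - s.values
        Z = sch.linkage(d[np.triu_indices(10, k=1)], method=scipy_method)
        for k in (8, 5, 3, 2):
            ours = agglomerate_subpartitions(g, np.arange(10), k, linkage=linkage)
            ref = sch.fcluster(Z, t=k, criterion="maxclust")
            # identical partitions up to label names
            pairs_ours = {(i, j) for i in range(10) for j in range(i + 1, 10)
                          if ours[i] == ours[j]}
            pairs_ref = {(i, j) for i in range(10) for j in range(i + 1, 10)
                         if ref[i] == ref[j]}
            assert pairs_ours == pairs_ref

    def test_strongest_edge_merges_first(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.9
        W[1, 2] = W[2, 1] = 0.1
        g = NeighborGraph(n_vertices=3, weights=W, k_neighbors=1)
        out = agglomerate_subpartitions(g, np.arange(3), 2, linkage="single")
        assert out[0] == out[1] != out[2]

    def test_k_final_too_large(self, small_sim):
        g = self._complete_graph(small_sim)
        with pytest.raises(ValueError):
            agglomerate_subpartitions(g, np.zeros(10, dtype=int), 2)


class TestChameleon:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        pts = np.vstack([c + rng.normal(0, 1, (15, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 15)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        sim = SimilarityMatrix(
            sample_ids=[str(i) for i in range(45)], values=1 - d / d.max()
        )
        sol = chameleon_cluster(sim, k_neighbors=10, k_final=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_all_singletons(self, small_sim):
        sol = chameleon_cluster(small_sim, k_neighbors=3, k_final=10, a=10)
        assert sol.n_clusters == 10

    def test_a_less_than_k_rejected(self, small_sim):
        with pytest.raises(ValueError):
            chameleon_cluster(small_sim, k_neighbors=3, k_final=5, a=2)

    def test_single_link_chaining_grows_with_subpartitions(self):
        """On gradient-structured community data, agglomerating many
        sub-partitions with single linkage concentrates samples in one big
        cluster (chaining): largest/median size ratio rises with a."""
        from interclust.evaluate import evenness_profile
        from interclust.similarity import bray_curtis_similarity, to_presence_absence
        from interclust.synthetic import CommunityConfig, simulate_community_matrix

        lo, hi = [], []
        for seed in range(5):
            cfg = CommunityConfig(n_clusters=4, plots_per_cluster=40,
                                  pool_size=30, p_in=0.9, p_out=0.02,
                                  gradient_strength=0.4, seed=seed)
            m, _, _ = simulate_community_matrix(cfg)
            sim = bray_curtis_similarity(to_presence_absence(m))
            for a, acc in ((8, lo), (80, hi)):
                sol = chameleon_cluster(sim, k_neighbors=15, k_final=8, a=a,
                                        linkage="single", seed=seed)
                sizes = np.sort(np.fromiter(sol.cluster_sizes().values(), dtype=float))
                acc.append(sizes[-1] / np.median(sizes))
        assert np.median(hi) > np.median(lo)

    def test_bit_reproducible(self, rng):
        s = random_similarity(40, rng)
        a = chameleon_cluster(s, k_neighbors=5, k_final=4, a=8, seed=3)
        b = chameleon_cluster(s, k_neighbors=5, k_final=4, a=8, seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert a.params == b.params
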