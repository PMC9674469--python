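"""Traditional clustering baselines: k-means, k-medoids, flexible-beta
UPGMA, and polythetic (splinter-group) division.

All operate either on coordinate data (k-means) or on a precomputed
similarity matrix, with dissimilarity taken as ``1 - similarity``
throughout.  Each returns a :class:`~interclust.datatypes.ClusterSolution`
with the generating parameters recorded.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import ClusterSolution, SimilarityMatrix

__all__ = [
    "kmeans_points",
    "kmedoids_dissimilarity",
    "flexible_upgma",
    "polythetic_division",
]


def kmeans_points(
    points: np.ndarray, k: int, seed: int = 0, n_restarts: int = 25
) -> ClusterSolution:
    """Lloyd's k-means on coordinates, best of ``n_restarts`` by WCSS.

    Each restart seeds k distinct data points as initial centroids (Forgy
    initialization) and iterates to convergence; the restart with the
    lowest within-cluster sum of squares wins.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="random", n_init=n_restarts,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(points)
    return ClusterSolution(
        labels=labels,
        params={"algorithm": "kmeans", "n_clusters": k, "seed": seed,
                "n_restarts": n_restarts, "wcss": float(km.inertia_)},
    )


def _kmedoids_once(
    s: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    n = s.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        # assign to the most similar medoid (ties: lowest medoid position)
        labels = np.argmax(s[:, medoids], axis=1)
        labels[medoids] = np.arange(k)  # a medoid belongs to its own cluster
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if len(members) == 0:
                # reseed an empty cluster with the sample least similar to
                # its current medoid
                fit = s[np.arange(n), medoids[labels]]
                fit[np.isin(np.arange(n), new_medoids)] = np.inf
                new_medoids[c] = int(np.argmin(fit))
                continue
            within = s[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmax(within))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmax(s[:, medoids], axis=1)
    labels[medoids] = np.arange(k)
    objective = float(s[np.arange(n), medoids[labels]].sum())
    return labels, medoids, objective


def kmedoids_dissimilarity(
    sim: SimilarityMatrix, k: int, seed: int = 0, n_restarts: int = 10
) -> ClusterSolution:
    """PAM-style k-medoids on a similarity matrix.

    Alternates assignment to the most similar medoid with medoid updates
    that maximize total within-cluster similarity; best of ``n_restarts``
    by the summed sample-to-medoid similarity.
    """
    n = sim.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best_labels, best_obj, best_medoids = None, -np.inf, None
    for _ in range(n_restarts):
        labels, medoids, obj = _kmedoids_once(sim.values, k, rng)
        if obj > best_obj:
            best_labels, best_obj, best_medoids = labels, obj, medoids
    return ClusterSolution(
        labels=best_labels,
        sample_ids=list(sim.sample_ids),
        params={"algorithm": "kmedoids", "n_clusters": k, "seed": seed,
                "n_restarts": n_restarts, "objective": best_obj,
                "medoids": [int(m) for m in best_medoids]},
    )


def upgma_merge_sequence(
    sim: SimilarityMatrix, beta: float = -0.1
) -> list[tuple[int, int, float]]:
    """Full flexible-beta agglomeration on ``d = 1 - s``.

    Lance-Williams recurrence with arithmetic (group-size-weighted)
    averaging: on merging clusters i and j,
    ``d(ij,k) = a_i d(i,k) + a_j d(j,k) + beta d(i,j)`` with
    ``a_i = (1 - beta) n_i / (n_i + n_j)``.  ``beta = 0`` is plain UPGMA.

    Returns the merge list as (cluster_a, cluster_b, height) over scipy-style
    cluster indices: originals are 0..n-1, the t-th merge creates n+t.
    """
    if not -1 < beta < 1:
        raise ValueError(f"beta must lie in (-1, 1), got {beta}")
    n = sim.n_samples
    d = 1.0 - sim.values
    np.fill_diagonal(d, np.inf)
    active = {i: (i, 1) for i in range(n)}  # row -> (scipy id, size)
    d = d.copy()
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        rows = sorted(active)
        sub = d[np.ix_(rows, rows)]
        flat = int(np.argmin(sub))
        ai, aj = divmod(flat, len(rows))
        if ai > aj:
            ai, aj = aj, ai
        ri, rj = rows[ai], rows[aj]
        height = float(d[ri, rj])
        id_i, n_i = active[ri]
        id_j, n_j = active[rj]
        alpha_i = (1 - beta) * n_i / (n_i + n_j)
        alpha_j = (1 - beta) * n_j / (n_i + n_j)
        for rk in rows:
            if rk in (ri, rj):
                continue
            d[ri, rk] = d[rk, ri] = (
                alpha_i * d[ri, rk] + alpha_j * d[rj, rk] + beta * height
            )
        merges.append((min(id_i, id_j), max(id_i, id_j), height))
        active[ri] = (next_id, n_i + n_j)
        del active[rj]
        d[rj, :] = np.inf
        d[:, rj] = np.inf
        next_id += 1
    return merges


def _cut_merges(merges: list[tuple[int, int, float]], n: int, k: int) -> np.ndarray:
    """Labels from replaying the first n-k merges (union-find)."""
    parent = list(range(n + len(merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _) in enumerate(merges[: n - k]):
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return labels


def flexible_upgma(
    sim: SimilarityMatrix, k: int, beta: float = -0.1
) -> ClusterSolution:
    """Flexible-beta UPGMA cut at ``k`` clusters (see
    :func:`upgma_merge_sequence`)."""
    n = sim.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    merges = upgma_merge_sequence(sim, beta=beta)
    labels = _cut_merges(merges, n, k)
    return ClusterSolution(
        labels=labels,
        sample_ids=list(sim.sample_ids),
        params={"algorithm": "upgma", "n_clusters": k, "beta": beta},
    )


def polythetic_division(
    sim: SimilarityMatrix, k: int, selection: str = "mean_dissimilarity"
) -> ClusterSolution:
    """Iterative splinter-group (polythetic divisive) clustering.

    Until ``k`` clusters exist: pick the cluster to divide (highest mean
    within-cluster dissimilarity, or largest diameter with
    ``selection='diameter'``); seed a splinter with the member of maximal
    mean dissimilarity to the rest; then repeatedly move the member whose
    mean dissimilarity to the remainder minus mean dissimilarity to the
    splinter is largest and positive.
    """
    if selection not in ("mean_dissimilarity", "diameter"):
        raise ValueError(f"unknown selection rule {selection!r}")
    n = sim.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = 1.0 - sim.values
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        # choose the cluster to divide
        def badness(members: list[int]) -> float:
            if len(members) < 2:
                return -np.inf
            sub = d[np.ix_(members, members)]
            if selection == "diameter":
                return float(sub.max())
            m = len(members)
            return float(sub.sum() / (m * (m - 1)))

        scores = [badness(c) for c in clusters]
        target = int(np.argmax(scores))
        members = clusters[target]
        # seed the splinter with the most estranged member
        sub = d[np.ix_(members, members)]
        mean_to_rest = sub.sum(axis=1) / (len(members) - 1)
        splinter = [members[int(np.argmax(mean_to_rest))]]
        remainder = [m for m in members if m != splinter[0]]
        while len(remainder) > 1:
            rem = np.array(remainder)
            spl = np.array(splinter)
            d_rem = d[np.ix_(rem, rem)].sum(axis=1) / (len(rem) - 1)
            d_spl = d[np.ix_(rem, spl)].mean(axis=1)
            delta = d_rem - d_spl
            best = int(np.argmax(delta))
            if delta[best] <= 0:
                break
            splinter.append(remainder.pop(best))
        clusters[target] = sorted(remainder)
        clusters.append(sorted(splinter))
    clusters.sort(key=min)
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(clusters):
        labels[c] = lab
    return ClusterSolution(
        labels=labels,
        sample_ids=list(sim.sample_ids),
        params={"algorithm": "divisive", "n_clusters": k, "selection": selection},
    )
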