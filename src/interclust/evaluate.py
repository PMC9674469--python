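"""Internal evaluation of clustering solutions.

Two headline metrics:

* misplacement rate — the proportion of samples whose nearest neighbor (by
  similarity) sits in a different cluster.  A sample with ties at the top
  counts as correctly placed if *any* tied nearest neighbor shares its
  cluster, so only unambiguous violations are penalized.
* homogeneity — the average pairwise within-cluster similarity, pooled over
  all unordered within-cluster pairs (singletons contribute none).  A
  per-cluster mean-of-means variant is available via ``per_cluster=True``.

Plus the evenness profile (ranked cluster sizes as a proportion of the
largest) used to detect chaining, and a sweep harness for parameter grids.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ClusterSolution, EvaluationReport, SimilarityMatrix

__all__ = [
    "misplacement_rate",
    "homogeneity",
    "evenness_profile",
    "evaluate_solution",
    "sweep",
]


def _labels_array(labels) -> np.ndarray:
    if isinstance(labels, ClusterSolution):
        labels = labels.labels
    return np.asarray(labels, dtype=int)


def misplacement_rate(sim: SimilarityMatrix, labels) -> float:
    labels = _labels_array(labels)
    n = sim.n_samples
    if n < 2:
        raise ValueError("misplacement rate requires at least 2 samples")
    if len(labels) != n:
        raise ValueError("labels length must match the similarity matrix")
    s = sim.values.copy()
    np.fill_diagonal(s, -np.inf)
    top = s.max(axis=1)
    misplaced = 0
    for i in range(n):
        tied = np.nonzero(s[i] == top[i])[0]
        if not np.any(labels[tied] == labels[i]):
            misplaced += 1
    return misplaced / n


def homogeneity(sim: SimilarityMatrix, labels, per_cluster: bool = False) -> float:
    labels = _labels_array(labels)
    if len(labels) != sim.n_samples:
        raise ValueError("labels length must match the similarity matrix")
    s = sim.values
    sums, counts = [], []
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        m = len(members)
        if m < 2:
            continue
        sub = s[np.ix_(members, members)]
        sums.append((sub.sum() - m) / 2.0)  # off-diagonal upper triangle
        counts.append(m * (m - 1) // 2)
    if not counts:
        raise ValueError("homogeneity undefined: all clusters are singletons")
    if per_cluster:
        return float(np.mean([sm / ct for sm, ct in zip(sums, counts)]))
    return float(sum(sums) / sum(counts))


def evenness_profile(labels) -> np.ndarray:
    """Cluster sizes ranked ascending, scaled by the largest size."""
    labels = _labels_array(labels)
    sizes = np.sort(np.unique(labels, return_counts=True)[1])
    return sizes / sizes[-1]


def evaluate_solution(sim: SimilarityMatrix, solution: ClusterSolution) -> EvaluationReport:
    labels = solution.labels
    try:
        h = homogeneity(sim, labels)
    except ValueError:
        h = float("nan")  # all-singleton solutions have no within pairs
    return EvaluationReport(
        misplacement_rate=misplacement_rate(sim, labels),
        homogeneity=h,
        cluster_sizes=solution.cluster_sizes(),
        evenness_profile=evenness_profile(labels),
        params=dict(solution.params),
    )


def sweep(
    sim: SimilarityMatrix,
    algorithm: Callable[..., ClusterSolution],
    grid: Sequence[dict],
    seed: int | None = None,
) -> pd.DataFrame:
    """Run ``algorithm(sim, **point)`` over a parameter grid.

    Returns one row per grid point with the point's parameters, both
    metrics, cluster-size extremes, and a ``chaining_suspect`` flag set when
    the largest cluster exceeds half the samples.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    rows = []
    for point in grid:
        kwargs = dict(point)
        if seed is not None and "seed" not in kwargs:
            kwargs["seed"] = seed
        sol = algorithm(sim, **kwargs)
        rep = evaluate_solution(sim, sol)
        sizes = list(rep.cluster_sizes.values())
        row = dict(point)
        row.update(
            n_clusters_found=len(sizes),
            misplacement_rate=rep.misplacement_rate,
            homogeneity=rep.homogeneity,
            largest_cluster=max(sizes),
            smallest_cluster=min(sizes),
            chaining_suspect=rep.chaining_suspect,
        )
        rows.append(row)
    return pd.DataFrame(rows)
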