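"""Synthetic data generators with the structure the analysis assumes.

Two families:

* bivariate Gaussian point clusters with uneven sizes — the classic setting
  in which centroid-based clustering splits dense clusters while merging
  sparse ones.  Presets ``fig1_i`` (sizes 30, 50, 500, 50, 70, 300) and
  ``fig1_ii`` (sizes 20, 100, 500, 20, 100, 500), both with isotropic
  sd = 1 and default centroids on a grid spaced 8 sd apart.
* presence-absence community matrices with planted cluster structure:
  cluster-private species occur in home plots with ``p_in`` and elsewhere
  with ``p_out``; optional species shared across all clusters; optional
  1-D gradient bleed that makes composition turn over continuously across
  cluster boundaries (elongated / chained similarity structure).

Generators are pure functions of their config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import CommunityMatrix, SimilarityMatrix, warn

__all__ = [
    "GaussianClusterConfig",
    "CommunityConfig",
    "gaussian_preset",
    "simulate_gaussian_clusters",
    "points_to_similarity",
    "simulate_community_matrix",
]

_PRESET_SIZES = {
    "fig1_i": (30, 50, 500, 50, 70, 300),
    "fig1_ii": (20, 100, 500, 20, 100, 500),
}

# grid of six centroids, all pairwise distances >= 8 (in units of sd=1)
_DEFAULT_CENTROIDS = (
    (0.0, 0.0), (8.0, 0.0), (16.0, 0.0),
    (0.0, 8.0), (8.0, 8.0), (16.0, 8.0),
)


@dataclass
class GaussianClusterConfig:
    centroids: Sequence[tuple[float, float]]
    sizes: Sequence[int]
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centroids) != len(self.sizes):
            raise ValueError("centroids and sizes must have equal length")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every cluster size must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def gaussian_preset(name: str, seed: int = 0) -> GaussianClusterConfig:
    """Named preset configs for the uneven-size six-cluster layouts."""
    if name not in _PRESET_SIZES:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(_PRESET_SIZES)}")
    return GaussianClusterConfig(
        centroids=_DEFAULT_CENTROIDS, sizes=_PRESET_SIZES[name], sd=1.0, seed=seed
    )


def simulate_gaussian_clusters(
    cfg: GaussianClusterConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points around each centroid with isotropic normal noise.

    Returns (points, true_labels); points of cluster c are
    ``centroid_c + Normal(0, sd^2 I)``.
    """
    rng = np.random.default_rng(cfg.seed)
    pts, labs = [], []
    for c, (centroid, size) in enumerate(zip(cfg.centroids, cfg.sizes)):
        pts.append(np.asarray(centroid, dtype=float) + cfg.sd * rng.standard_normal((size, 2)))
        labs.append(np.full(size, c))
    return np.vstack(pts), np.concatenate(labs)


def points_to_similarity(
    points: np.ndarray, kernel: str = "linear", bandwidth: float | None = None
) -> SimilarityMatrix:
    """Similarity matrix from coordinates.

    ``linear``: ``s = 1 - d / max(d)`` (the two most distant points get 0).
    ``gaussian``: ``s = exp(-d^2 / (2 bw^2))`` with bandwidth defaulting to
    the median pairwise distance.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    d = pdist(points)
    if kernel == "linear":
        dmax = d.max()
        if dmax == 0:
            warn("all points identical; similarity is 1 everywhere")
            values = np.ones((n, n))
        else:
            values = 1.0 - squareform(d / dmax)
            np.fill_diagonal(values, 1.0)
    elif kernel == "gaussian":
        bw = bandwidth if bandwidth is not None else float(np.median(d))
        if bw <= 0:
            warn("degenerate bandwidth; similarity is 1 everywhere")
            values = np.ones((n, n))
        else:
            values = squareform(np.exp(-(d**2) / (2 * bw**2)))
            np.fill_diagonal(values, 1.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return SimilarityMatrix(sample_ids=[str(i) for i in range(n)], values=values)


@dataclass
class CommunityConfig:
    """Parameters of the planted-structure community generator.

    ``gradient_strength`` 0 gives discrete blocks; positive values widen
    the bleed of each cluster's species across neighboring positions on a
    latent 1-D gradient, producing chained/elongated similarity structure.
    """

    n_clusters: int = 3
    plots_per_cluster: int | Sequence[int] = 30
    pool_size: int | Sequence[int] = 40
    p_in: float = 0.9
    p_out: float = 0.02
    n_shared: int = 0
    gradient_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        for p, name in ((self.p_in, "p_in"), (self.p_out, "p_out")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out for recoverable structure")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")

    def sizes(self) -> list[int]:
        if isinstance(self.plots_per_cluster, int):
            return [self.plots_per_cluster] * self.n_clusters
        return list(self.plots_per_cluster)

    def pools(self) -> list[int]:
        if isinstance(self.pool_size, int):
            return [self.pool_size] * self.n_clusters
        return list(self.pool_size)


def simulate_community_matrix(
    cfg: CommunityConfig,
) -> tuple[CommunityMatrix, np.ndarray, dict[int, list[str]]]:
    """Bernoulli presence-absence draws with planted cluster structure.

    Returns (matrix, true_labels, planted_diagnostics) where
    ``planted_diagnostics[c]`` lists cluster c's private species.  Plots
    are guaranteed nonempty (empty rows are redrawn, up to 100 attempts).

    With ``gradient_strength g > 0``, each plot gets a position on a latent
    [0, 1] gradient (cluster c occupies the segment [c/k, (c+1)/k]) and a
    cluster's species occur beyond their home segment with probability
    decaying as ``exp(-d^2 / (2 (g/k)^2))`` in the gradient distance ``d``
    to the segment — larger g means more compositional bleed across
    boundaries, hence more nearest neighbors in adjacent clusters.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes()
    pools = cfg.pools()
    if len(sizes) != cfg.n_clusters or len(pools) != cfg.n_clusters:
        raise ValueError("per-cluster lists must have n_clusters entries")
    k = cfg.n_clusters
    labels = np.concatenate([np.full(s, c) for c, s in enumerate(sizes)])
    n_plots = int(labels.size)

    species_ids: list[str] = []
    species_cluster: list[int] = []  # -1 for shared
    planted: dict[int, list[str]] = {}
    for c in range(k):
        names = [f"sp_c{c}_{j}" for j in range(pools[c])]
        planted[c] = names
        species_ids.extend(names)
        species_cluster.extend([c] * pools[c])
    species_ids.extend(f"sp_shared_{j}" for j in range(cfg.n_shared))
    species_cluster.extend([-1] * cfg.n_shared)
    species_cluster_arr = np.array(species_cluster)

    # occurrence probability per (plot, species)
    if cfg.gradient_strength > 0:
        pos = np.concatenate(
            [rng.uniform(c / k, (c + 1) / k, size=s) for c, s in enumerate(sizes)]
        )
        sigma = cfg.gradient_strength / k
        lo = species_cluster_arr / k
        hi = (species_cluster_arr + 1) / k
        dist = np.maximum(0.0, np.maximum(lo[None, :] - pos[:, None],
                                          pos[:, None] - hi[None, :]))
        kernel = np.exp(-(dist**2) / (2 * sigma**2))
        prob = cfg.p_out + (cfg.p_in - cfg.p_out) * kernel
    else:
        same = species_cluster_arr[None, :] == labels[:, None]
        prob = np.where(same, cfg.p_in, cfg.p_out)
    prob[:, species_cluster_arr == -1] = cfg.p_in  # shared species everywhere

    if np.all(prob == 0):
        raise ValueError("all occurrence probabilities are zero; plots cannot be nonempty")
    values = (rng.random(prob.shape) < prob).astype(float)
    for i in range(n_plots):
        attempts = 0
        while values[i].sum() == 0:
            attempts += 1
            if attempts > 100:
                raise RuntimeError(f"plot {i} stayed empty after 100 redraws")
            values[i] = (rng.random(prob.shape[1]) < prob[i]).astype(float)

    matrix = CommunityMatrix(
        plot_ids=[f"plot_{i}" for i in range(n_plots)],
        species_ids=species_ids,
        values=values,
    )
    return matrix, labels, planted
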