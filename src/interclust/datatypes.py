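"""Core containers shared across the pipeline.

The objects here are thin, validated wrappers around numpy arrays plus
ordered identifier lists.  Order is meaningful everywhere: the index order
of a file defines the index order of the matrix, and labels are always
aligned with ``sample_ids``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CommunityMatrix",
    "SimilarityMatrix",
    "NeighborGraph",
    "ClusterSolution",
    "ReferenceClassification",
    "EvaluationReport",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)
    return ids


@dataclass
class CommunityMatrix:
    """Plot x species abundance or incidence matrix.

    ``values[i, j]`` is the abundance (or 0/1 incidence) of species
    ``species_ids[j]`` in plot ``plot_ids[i]``.  Values must be
    non-negative; ``is_binary`` records whether every entry is 0 or 1.
    """

    plot_ids: list[str]
    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.plot_ids = _check_unique(self.plot_ids, "plot")
        self.species_ids = _check_unique(self.species_ids, "species")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("community matrix must be two-dimensional")
        if self.values.shape != (len(self.plot_ids), len(self.species_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.plot_ids)} plots x {len(self.species_ids)} species"
            )
        if np.any(self.values < 0):
            raise ValueError("community matrix values must be non-negative")

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def empty_plots(self) -> list[str]:
        """Identifiers of plots with no species after binarization."""
        mask = ~np.any(self.values > 0, axis=1)
        return [p for p, m in zip(self.plot_ids, mask) if m]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1] with unit diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}")
        if n == 0:
            raise ValueError("similarity matrix must be non-empty")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-9:
            raise ValueError(f"similarity matrix asymmetric (max deviation {asym:.3g})")
        # symmetrize exactly and clip away float fuzz
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("similarity diagonal must be 1")
        np.fill_diagonal(self.values, 1.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class NeighborGraph:
    """Weighted undirected k-nearest-neighbor graph over samples.

    Stored as a dense symmetric weight matrix with zeros for absent edges;
    desk-scale problems (a few thousand vertices) make this the simplest
    faithful representation.  Self-edges are never present.
    """

    n_vertices: int
    weights: np.ndarray  # dense symmetric, 0 where no edge
    k_neighbors: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_vertices, self.n_vertices):
            raise ValueError("weight matrix shape mismatch")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-edges are not allowed")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("neighbor graph must be undirected")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("edge weights must lie in [0, 1]")

    def edges(self) -> list[tuple[int, int, float]]:
        """Edge list with i < j, sorted lexicographically."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)


@dataclass
class ClusterSolution:
    """Per-sample integer labels plus the parameters that generated them."""

    labels: np.ndarray
    params: dict = field(default_factory=dict)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids length must match labels")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


@dataclass
class ReferenceClassification:
    """Expert typology: class name -> set of indicative species."""

    classes: Mapping[str, set]
    class_order: list[str] | None = None

    def __post_init__(self) -> None:
        names = list(self.classes)
        _check_unique(names, "class")
        for name, sp in self.classes.items():
            if not sp:
                raise ValueError(f"reference class {name!r} has no species")
        if self.class_order is None:
            self.class_order = names


@dataclass
class EvaluationReport:
    """Internal-metric summary of one clustering solution."""

    misplacement_rate: float
    homogeneity: float
    cluster_sizes: dict[int, int]
    evenness_profile: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.evenness_profile = np.asarray(self.evenness_profile, dtype=float)
        if len(self.evenness_profile) and not np.isclose(self.evenness_profile[-1], 1.0):
            raise ValueError("evenness profile must end at 1")
        if np.any(np.diff(self.evenness_profile) < 0):
            raise ValueError("evenness profile must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return int(sum(self.cluster_sizes.values()))

    @property
    def chaining_suspect(self) -> bool:
        """True when the largest cluster holds more than half the samples."""
        if not self.cluster_sizes:
            return False
        return max(self.cluster_sizes.values()) > 0.5 * self.n_samples


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
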