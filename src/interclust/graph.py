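"""Two-phase graph-theoretic clustering (Chameleon-style).

Phase 1 models the samples as a sparse k-nearest-neighbor graph weighted by
pairwise similarity and partitions it into ``a`` sub-partitions by recursive
min-weight bisection: each bisection seeks to minimize the total similarity
of dissolved (cut) links, subject to a balance floor.  Phase 2 optionally
merges sub-partitions back to ``k`` final clusters with a greedy
agglomerative pass using single or complete linkage evaluated over graph
edges.

The partitioner is a deterministic heuristic: candidate splits from a
spectral (Fiedler-vector) sweep and from region growing, each refined by
Fiduccia-Mattheyses-style boundary moves.  Ties break on the lowest vertex
index throughout, so results are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg

from .datatypes import ClusterSolution, NeighborGraph, SimilarityMatrix

__all__ = [
    "build_knn_graph",
    "partition_graph",
    "agglomerate_subpartitions",
    "chameleon_cluster",
]

# each side of a bisection must hold at least this fraction of the vertices;
# unconstrained min-cut degenerates to shaving off single vertices
DEFAULT_BALANCE_FLOOR = 0.10


def build_knn_graph(sim: SimilarityMatrix, k_neighbors: int) -> NeighborGraph:
    """Union-symmetrized k-nearest-neighbor graph from a similarity matrix.

    Each vertex contributes edges to its ``k_neighbors`` most similar other
    vertices; ties at the k-th rank include all tied samples.  An edge is
    kept if either endpoint selects it (union symmetrization), which
    preserves connectivity for low-degree outliers.
    """
    n = sim.n_samples
    if not 1 <= k_neighbors <= n - 1:
        raise ValueError(f"k_neighbors must be in [1, {n - 1}], got {k_neighbors}")
    s = sim.values.copy()
    np.fill_diagonal(s, -np.inf)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        row = s[i]
        # similarity of the k-th most similar neighbor; include all ties
        kth = np.partition(row, n - k_neighbors)[n - k_neighbors]
        adj[i, row >= kth] = True
    adj |= adj.T
    weights = np.where(adj, sim.values, 0.0)
    np.fill_diagonal(weights, 0.0)
    return NeighborGraph(n_vertices=n, weights=weights, k_neighbors=k_neighbors)


# ---------------------------------------------------------------------------
# phase 1: recursive min-weight bisection
# ---------------------------------------------------------------------------


def _fiedler_order(W: np.ndarray) -> np.ndarray:
    """Vertex order along the Fiedler vector of the weighted Laplacian."""
    n = W.shape[0]
    d = W.sum(axis=1)
    L = np.diag(d) - W
    if n <= 1500:
        # dense solve is faster than shift-invert at desk scale
        vals, vecs = scipy.linalg.eigh(L, subset_by_index=[0, 1])
        fiedler = vecs[:, 1]
    else:
        # deterministic start vector; sigma=0 shift-invert targets the
        # smallest eigenpairs of the (PSD) Laplacian
        v0 = np.linspace(1.0, 2.0, n)
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(
                scipy.sparse.csr_matrix(L), k=2, sigma=0, v0=v0
            )
            fiedler = vecs[:, np.argsort(vals)[1]]
        except Exception:
            vals, vecs = scipy.linalg.eigh(L)
            fiedler = vecs[:, 1]
    # stable sort with index tie-break
    return np.lexsort((np.arange(n), fiedler))


def _sweep_cut(W: np.ndarray, order: np.ndarray, floor: int) -> np.ndarray | None:
    """Best prefix cut along an ordering, respecting the balance floor."""
    n = W.shape[0]
    if n - floor < floor:
        return None
    inA = np.zeros(n, dtype=bool)
    cut = 0.0
    best_cut, best_p = np.inf, None
    for p in range(n - 1):
        v = order[p]
        # moving v from B to A: edges v-B join the cut, edges v-A leave it
        cut += W[v, ~inA].sum() - W[v, inA].sum()
        inA[v] = True
        size_a = p + 1
        if floor <= size_a <= n - floor and cut < best_cut - 1e-15:
            best_cut, best_p = cut, p
    if best_p is None:
        return None
    mask = np.zeros(n, dtype=bool)
    mask[order[: best_p + 1]] = True
    return mask


def _region_grow(W: np.ndarray, seed: int) -> np.ndarray:
    """Prim-style ordering: repeatedly absorb the outside vertex with the
    strongest connection to the grown region (ties: lowest index)."""
    n = W.shape[0]
    order = np.empty(n, dtype=int)
    order[0] = seed
    in_region = np.zeros(n, dtype=bool)
    in_region[seed] = True
    attach = W[seed].copy()
    attach[seed] = -np.inf
    for p in range(1, n):
        v = int(np.argmax(attach))  # argmax takes the first (lowest index) tie
        order[p] = v
        in_region[v] = True
        attach += W[v]
        attach[in_region] = -np.inf
    return order


def _refine_fm(W: np.ndarray, mask: np.ndarray, floor: int, max_passes: int = 10) -> np.ndarray:
    """Fiduccia-Mattheyses refinement: passes of single-vertex moves.

    Within a pass every vertex moves at most once (best gain first, balance
    respected); the pass commits the best prefix of moves seen.  Gain of
    moving ``v`` is the cut-weight decrease ``w(v, other side) - w(v, own
    side)``.
    """
    n = W.shape[0]
    mask = mask.copy()
    for _ in range(max_passes):
        side = mask.copy()
        size_a = int(side.sum())
        # gain[v] = w(v, other side) - w(v, own side)
        own = (W * side).sum(axis=1)
        other = (W * ~side).sum(axis=1)
        gain = np.where(side, other - own, own - other)
        locked = np.zeros(n, dtype=bool)
        moves: list[int] = []
        gains: list[float] = []
        cur_size = size_a
        for _ in range(n):
            cand = ~locked
            if cur_size <= floor:
                cand &= ~side  # only B->A moves keep A above the floor
            if n - cur_size <= floor:
                cand &= side
            if not cand.any():
                break
            g = np.where(cand, gain, -np.inf)
            v = int(np.argmax(g))
            if not np.isfinite(g[v]):
                break
            moves.append(v)
            gains.append(float(gain[v]))
            # apply the move
            was_a = side[v]
            side[v] = not was_a
            cur_size += -1 if was_a else 1
            locked[v] = True
            # update gains of unlocked neighbors
            upd = (W[v] > 0) & ~locked
            gain[upd] += np.where(side[upd] == side[v], -2.0, 2.0) * W[v, upd]
        if not moves:
            break
        prefix = np.cumsum(gains)
        best = int(np.argmax(prefix))
        if prefix[best] <= 1e-12:
            break
        for v in moves[: best + 1]:
            mask[v] = ~mask[v]
    return mask


def _cut_stats(W: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    cross = W[np.ix_(mask, ~mask)]
    return float(cross.sum()), int((cross > 0).sum())


def _best_bisection(
    W: np.ndarray, balance_floor: float
) -> tuple[np.ndarray, float, int]:
    """Best found bisection of a (sub)graph given as a dense weight matrix.

    Returns (mask of side A, cut weight, number of dissolved edges).
    """
    n = W.shape[0]
    if n < 2:
        raise ValueError("cannot bisect fewer than 2 vertices")
    floor = max(1, int(np.ceil(balance_floor * n)))
    n_comp, comp = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(W), directed=False
    )
    if n_comp > 1:
        # zero-cut split: pack components into two sides, largest first into
        # the lighter side, so disconnected pieces are separated for free
        sizes = np.bincount(comp)
        order = np.lexsort((np.arange(n_comp), -sizes))
        side_tot = [0, 0]
        side_of = np.zeros(n_comp, dtype=int)
        for c in order:
            s = 0 if side_tot[0] <= side_tot[1] else 1
            side_of[c] = s
            side_tot[s] += sizes[c]
        mask = side_of[comp] == 0
        if mask.all() or not mask.any():  # single nonempty side cannot happen for n_comp>1
            mask[:] = False
            mask[comp == comp[0]] = True
        return mask, 0.0, 0

    candidates: list[np.ndarray] = []
    order = _fiedler_order(W)
    m = _sweep_cut(W, order, floor)
    if m is not None:
        candidates.append(m)
    # region growing: from every vertex on small subgraphs, else from the
    # heaviest and lightest vertices only
    deg = W.sum(axis=1)
    if n <= 48:
        seeds = range(n)
    else:
        seeds = {int(np.argmax(deg)), int(np.argmin(deg))}
    for seed in seeds:
        grow = _region_grow(W, seed)
        m = _sweep_cut(W, grow, floor)
        if m is not None:
            candidates.append(m)
    if not candidates:
        # floor infeasible (tiny set): plain halving on the Fiedler order
        mask = np.zeros(n, dtype=bool)
        mask[order[: n // 2]] = True
        candidates.append(mask)
    best_mask, best_cut, best_edges = None, np.inf, 0
    for m in candidates:
        m = _refine_fm(W, m, floor)
        cut, ne = _cut_stats(W, m)
        if cut < best_cut - 1e-12:
            best_mask, best_cut, best_edges = m, cut, ne
    return best_mask, best_cut, best_edges


def partition_graph(
    g: NeighborGraph,
    a: int,
    prioritize_large: bool = False,
    seed: int | None = None,
    balance_floor: float = DEFAULT_BALANCE_FLOOR,
    selection: str = "total_cut",
) -> np.ndarray:
    """Dissolve links to split the graph into ``a`` sub-partitions.

    Recursive bisection; each bisection heuristically minimizes the summed
    similarity of dissolved links subject to the balance floor.  When
    ``prioritize_large`` the largest current sub-partition is bisected next;
    otherwise the sub-partition whose best bisection dissolves the least
    total similarity is chosen (``selection='total_cut'``, the greedy step
    toward minimizing the summed weight of all dissolved links), or the
    least similarity per dissolved link (``selection='per_edge'``).
    ``seed`` is accepted for interface uniformity; the procedure is
    deterministic.
    """
    if selection not in ("total_cut", "per_edge"):
        raise ValueError(f"unknown selection rule {selection!r}")
    n = g.n_vertices
    if not 1 <= a <= n:
        raise ValueError(f"number of sub-partitions must be in [1, {n}], got {a}")
    W = g.weights
    parts: list[np.ndarray] = [np.arange(n)]
    # cache: index of part -> (maskA, cut, n_edges), computed lazily
    plans: dict[int, tuple[np.ndarray, float, int]] = {}

    def plan(idx: int) -> tuple[np.ndarray, float, int]:
        if idx not in plans:
            verts = parts[idx]
            sub = W[np.ix_(verts, verts)]
            plans[idx] = _best_bisection(sub, balance_floor)
        return plans[idx]

    while len(parts) < a:
        splittable = [i for i, p in enumerate(parts) if len(p) >= 2]
        if prioritize_large:
            best = max(
                splittable,
                key=lambda i: (len(parts[i]), -int(parts[i].min())),
            )
        else:
            def score(i: int) -> tuple[float, int]:
                _, cut, ne = plan(i)
                val = cut / max(ne, 1) if selection == "per_edge" else cut
                return (val, int(parts[i].min()))

            best = min(splittable, key=score)
        mask, _, _ = plan(best)
        verts = parts[best]
        left, right = verts[mask], verts[~mask]
        parts[best] = left
        plans.pop(best, None)
        parts.append(right)
        # cache keys are positional; drop stale entries for safety
        plans = {i: v for i, v in plans.items() if i != best and i < len(parts) - 1}

    # deterministic labelling: parts ordered by their lowest vertex
    parts.sort(key=lambda p: int(p.min()))
    labels = np.empty(n, dtype=int)
    for lab, p in enumerate(parts):
        labels[p] = lab
    return labels


# ---------------------------------------------------------------------------
# phase 2: agglomerative merging of sub-partitions
# ---------------------------------------------------------------------------


def _linkage_value(
    W: np.ndarray, A: np.ndarray, B: np.ndarray, linkage: str
) -> float:
    cross = W[np.ix_(A, B)]
    if not (cross > 0).any():
        return -np.inf  # no connecting edge
    if linkage == "single":
        return float(cross.max())
    # complete: min over all joining pairs, absent edges contribute 0
    return float(cross.min())


def agglomerate_subpartitions(
    g: NeighborGraph,
    labels: np.ndarray,
    k_final: int,
    linkage: str = "complete",
    sim: SimilarityMatrix | None = None,
    use_graph_edges: bool = True,
) -> np.ndarray:
    """Greedily merge sub-partitions down to ``k_final`` clusters.

    At each step the pair with the highest linkage similarity merges.
    Single linkage is the maximum edge weight joining two clusters; complete
    linkage the minimum over all joining pairs with absent graph edges
    counted as 0.  Pairs with no connecting edge merge only when no
    connected pair remains.  With ``use_graph_edges=False`` linkage is
    evaluated on the full similarity matrix instead (requires ``sim``).
    """
    if linkage not in ("single", "complete"):
        raise ValueError(f"linkage must be 'single' or 'complete', got {linkage!r}")
    labels = np.asarray(labels, dtype=int)
    if use_graph_edges:
        W = g.weights
    else:
        if sim is None:
            raise ValueError("use_graph_edges=False requires the similarity matrix")
        W = sim.values.copy()
        np.fill_diagonal(W, 0.0)
    uniq = np.unique(labels)
    clusters: dict[int, np.ndarray] = {int(c): np.nonzero(labels == c)[0] for c in uniq}
    if k_final > len(clusters):
        raise ValueError(f"k_final={k_final} exceeds current cluster count {len(clusters)}")
    while len(clusters) > k_final:
        keys = sorted(clusters)
        best_pair, best_val = None, -np.inf
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                v = _linkage_value(W, clusters[a], clusters[b], linkage)
                if v > best_val:
                    best_val, best_pair = v, (a, b)
        if best_pair is None or not np.isfinite(best_val):
            # no connected pair remains: merge the lexicographically first pair
            best_pair = (keys[0], keys[1])
        a, b = best_pair
        clusters[a] = np.sort(np.concatenate([clusters[a], clusters[b]]))
        del clusters[b]
    out = np.empty_like(labels)
    for lab, key in enumerate(sorted(clusters, key=lambda k: int(clusters[k].min()))):
        out[clusters[key]] = lab
    return out


def chameleon_cluster(
    sim: SimilarityMatrix,
    k_neighbors: int,
    k_final: int,
    a: int | None = None,
    linkage: str = "complete",
    prioritize_large: bool = False,
    seed: int | None = None,
    balance_floor: float = DEFAULT_BALANCE_FLOOR,
    use_graph_edges: bool = True,
) -> ClusterSolution:
    """Full two-phase pipeline: k-NN graph -> sub-partitions -> clusters.

    ``a`` defaults to ``k_final`` (agglomerative phase omitted); it must
    satisfy ``k_final <= a <= n``.
    """
    n = sim.n_samples
    if a is None:
        a = k_final
    if a < k_final:
        raise ValueError(f"number of sub-partitions a={a} must be >= k_final={k_final}")
    g = build_knn_graph(sim, k_neighbors)
    sub = partition_graph(g, a, prioritize_large=prioritize_large, seed=seed,
                          balance_floor=balance_floor)
    if a == k_final:
        labels = sub
    else:
        labels = agglomerate_subpartitions(
            g, sub, k_final, linkage=linkage, sim=sim, use_graph_edges=use_graph_edges
        )
    return ClusterSolution(
        labels=labels,
        sample_ids=list(sim.sample_ids),
        params={
            "algorithm": "chameleon",
            "k_neighbors": k_neighbors,
            "n_subpartitions": a,
            "n_clusters": k_final,
            "linkage": linkage if a != k_final else "none",
            "prioritize_large": prioritize_large,
            "seed": seed,
        },
    )
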