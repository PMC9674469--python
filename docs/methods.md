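# Methods

## Problem setting

Vegetation classification clusters plot samples (relevés) — fixed-area
field records of the vascular species present — into community types.
Most clustering algorithms assume roughly hyperspheroidal clusters and
evaluate solutions by central tendency (within-cluster homogeneity).  Real
plot databases are unevenly sampled and compositionally irregular, so an
algorithm optimizing central tendency can split dense clusters while
merging sparse ones.  `interclust` implements an
interconnectivity-oriented alternative — a two-phase graph-theoretic
(Chameleon-style) clustering — together with three traditional baselines
and the evaluation machinery needed to compare them.

## Similarity

Cover-abundance values are binarized to presence-absence (entry 1 iff the
species was recorded), removing observer bias in abundance estimates.
Pairwise similarity between plots is the Sørensen(-Dice) index

    s(i, j) = 2a / (2a + b + c)

with `a` the number of shared species and `b`, `c` the species unique to
each plot; on binary data this equals 1 − Bray-Curtis dissimilarity.
Plots with zero species are a hard error (similarity is undefined and
emptiness signals upstream corruption); species observed in no plot are
dropped with a warning because they cannot change any pairwise score but
would distort frequency-based diagnostics.  Dissimilarity is `1 − s`
throughout.

## Two-phase graph clustering

**Phase 1 (partitioning).**  The samples form a k-nearest-neighbor graph:
each vertex links to its `k_neighbors` most similar other vertices (ties
at the k-th rank are all included), edges weighted by similarity, and the
edge set is the union over both endpoints' choices.  Union (not mutual)
symmetrization keeps low-degree outliers connected.  The graph is split
into `a` sub-partitions by recursive bisection, each bisection seeking to
minimize the total similarity of dissolved (cut) links subject to a
balance floor: each side must hold at least 10% of the bisected vertex set
(configurable), because unconstrained min-cut degenerates to shaving
single vertices.  A bisection is found by generating candidate splits from
a spectral sweep (best prefix cut along the Fiedler vector of the weighted
graph Laplacian) and from Prim-style region growing, then refining each
with Fiduccia–Mattheyses passes (locked single-vertex moves, best prefix
committed); the best candidate by cut weight wins.  On graphs of up to 12
vertices this heuristic matched an exhaustive enumeration of all
balance-feasible bipartitions in 100/100 random trials.

Which sub-partition to bisect next: with `prioritize_large`, always the
largest; otherwise the part whose best bisection dissolves the least
*total* similarity — the greedy step toward minimizing the summed weight
of all dissolved links.  A per-edge alternative (least dissolved
similarity per cut link) is available as `selection='per_edge'` but is not
the default: on uneven-density data it prefers shaving outliers off tight
small clusters (per-edge cost ≈ within-cluster weight) over the clean
few-edge splits between genuinely distinct groups, leaving giant merged
sub-partitions.

Disconnected parts are split along connected components at zero cost.
All ties break on the lowest vertex index, so the procedure is
deterministic and bit-reproducible; the `seed` parameter exists for
interface uniformity.

**Phase 2 (agglomeration).**  Sub-partitions are merged greedily until
`k_final` clusters remain; at each step the pair with the highest linkage
similarity merges.  Single linkage is the maximum edge weight joining two
clusters; complete linkage is the minimum over all joining pairs, with
pairs lacking a graph edge contributing 0.  Cluster pairs with no
connecting edge at all rank −∞ and merge only when no connected pair
remains.  Linkage is evaluated over graph edges by default (phase 2 stays
a pure graph operation); `use_graph_edges=False` evaluates it on the full
similarity matrix instead.  Setting `a = k_final` omits the agglomerative
phase entirely.  On a complete graph with singleton sub-partitions the
procedure reproduces textbook single-/complete-linkage agglomeration
exactly.

Default linkage is complete: single linkage with many sub-partitions
chains (one cluster absorbs most samples through chains of close links),
and the package's own gradient-data experiments reproduce that symptom.

## Baselines

* **k-means** (coordinate data): Lloyd iteration from k distinct randomly
  chosen data points (Forgy initialization), best of `n_restarts` (default
  25) by within-cluster sum of squares, via scikit-learn.  Random-point
  seeding is deliberate: with very uneven cluster sizes the sparse
  clusters are rarely seeded, which is exactly the classical failure mode
  the package's comparisons probe.
* **k-medoids** (similarity data): PAM-style alternation between
  assignment to the most similar medoid and medoid updates maximizing
  within-cluster total similarity, best of `n_restarts`; the
  nonhierarchical allocation stand-in for similarity matrices.
* **Flexible-beta UPGMA**: Lance–Williams recurrence with arithmetic
  (group-size-weighted) coefficients `alpha_i = (1−beta)·n_i/(n_i+n_j)`
  and mixing parameter `beta` (default −0.1, common ecological practice;
  `beta = 0` is plain UPGMA).  Merge heights are monotone for `beta ≤ 0`.
* **Polythetic division**: splinter-group division — the cluster with the
  highest mean within-cluster dissimilarity (diameter-based selection
  available) is divided by seeding a splinter with its most estranged
  member and iteratively moving members whose mean dissimilarity to the
  remainder exceeds that to the splinter.

## Evaluation metrics

* **Misplacement rate**: the fraction of samples whose nearest neighbor
  (highest similarity) lies in a different cluster.  Ties: a sample counts
  as placed if *any* tied nearest neighbor shares its cluster — only
  unambiguous violations are penalized.
* **Homogeneity**: mean similarity pooled over all unordered
  within-cluster pairs (singleton clusters contribute none; undefined and
  an error when every cluster is a singleton).  A per-cluster
  mean-of-means variant is exposed (`per_cluster=True`) since pooling
  versus cluster-averaging is a genuine open choice; pooled is the default
  and is what all reported numbers use.
* **Evenness profile**: cluster sizes ranked ascending and scaled by the
  largest — a flat profile near 1 means even clusters, a long low tail
  means chaining.  The sweep harness flags solutions whose largest cluster
  exceeds 50% of the samples as chaining-suspect; the threshold
  operationalizes an otherwise qualitative judgement.

Merging two clusters can only grow each sample's co-clustered neighbor
set, so misplacement is monotone non-increasing under merges; this is
asserted as a property test.

## Diagnostic species and reference comparison

For every (species, cluster) pair with `x` in-cluster occurrences, cluster
size `m`, total occurrences `X`, and `N` plots:

* **Hypergeometric criterion**: lower-tail probability `P(H < x)` with
  `H ~ Hypergeom(N, X, m)`; diagnostic when it exceeds 0.999.  The strict
  tail (`<`) makes the criterion an upper-tail test at level 0.001;
  `P(H ≤ x)` is exposed as an option.
* **Standardized phi**: the 2×2 association coefficient
  `phi = (N·x − m·X) / sqrt(m·X·(N−m)·(N−X))`, recomputed after rescaling
  the target cluster to relative size `1/k` (configurable) while
  preserving in- and out-of-cluster relative frequencies, so fidelity is
  comparable across cluster sizes; diagnostic when `phi ≥ 0.35`.  With
  equal observed cluster sizes the standardized and raw values coincide.
  Species present everywhere or nowhere get `phi = 0`.

No multiple-testing correction is applied by default, matching the
raw-threshold convention of diagnostic-species practice; a Bonferroni
option exists.  Summary counts report (species, cluster) pairs by default
with a unique-species option, plus the joint count with in-cluster
frequency ≥ 0.3 and the median frequency of those passers.

The reference confusion matrix compares a cluster solution against an
expert typology given as class → indicative-species lists: entry
(class, cluster) is the proportion of the class's species identified as
diagnostic of that cluster.  Rows follow the reference file's order.

## Synthetic data

**Gaussian point clusters** emulate uneven-density point data: isotropic
bivariate normal noise (sd = 1) around six centroids, presets `fig1_i`
(sizes 30, 50, 500, 50, 70, 300) and `fig1_ii` (20, 100, 500, 20, 100,
500).  Default centroids sit on a 2×3 grid with 8·sd spacing (all pairwise
distances ≥ 6·sd); centroid coordinates are configurable.  Coordinates
map to similarity by `s = 1 − d/max(d)` (Euclidean); a Gaussian-kernel
alternative is provided since the choice of transformation is open.

**Community matrices** are Bernoulli presence-absence draws: each cluster
has a pool of private species occurring with `p_in` (default 0.9) in home
plots and `p_out` (default 0.02) elsewhere, plus optional species shared
everywhere at `p_in`.  With `gradient_strength g > 0`, plots get positions
on a latent 1-D gradient (cluster c occupies segment [c/k, (c+1)/k]) and
species occurrence decays beyond the home segment as
`exp(−d²/(2σ²))` with `σ = g/k` — the flat-top kernel keeps the g = 0
limit exactly block-structured while positive g bleeds composition across
boundaries, producing the chained/elongated similarity structure of a
compositional continuum.  The count of plots whose nearest neighbor falls
in an adjacent true cluster rises with g up to g ≈ 0.4–0.5 and then
saturates: once the turnover length exceeds a cluster's gradient extent,
bleed is no longer specifically "adjacent".  Plots are guaranteed
nonempty (empty rows redrawn, at most 100 attempts, then an error —
silent infinite loops are worse than failure).  Generators are pure
functions of config + seed.

What the generators do **not** emulate: spatial autocorrelation,
cover-abundance values, observer bias, and realistic species-abundance
distributions.  Passing tests on these data show the algorithms and
metrics behave as designed under known structure; they do not certify
performance on any particular field dataset.

## Study conditions used by the tests and the acceptance script

Problem sizes are chosen to exercise each property at desk scale:

* metric/similarity/tail oracles: 100 random instances of n ≤ 20 plots;
* partitioner optimality: 100 random sparse graphs of 6–12 vertices
  against exhaustive bipartition enumeration;
* linkage equivalence: 10-sample matrices, all cut levels, 5 matrices;
* Gaussian contrast and neighborhood-size trend: the full `fig1_ii`
  preset (n = 1240), 10 seeds, neighborhoods {15, 50, 150, 500};
* classification-detail trend: 600-plot communities (6 clusters × 100
  plots, 40 private species each, 20 shared, g = 0.5), k ∈ {5, 10, 20,
  40}, 10 seeds, chameleon run at `a = 2k` with complete linkage (the
  preferred configuration after the chaining finding) and neighborhood 30;
* diagnostic recovery: 3 clusters × 30 plots, 30 private species each,
  `p_in = 0.9`, `p_out = 0.02`, 10 seeds.

## Numerical choices and limitations

* CLUTO-format writes use 6 fixed decimals (round-trip error ≤ 5·10⁻⁷);
  a missing unit diagonal on read is coerced to 1 with a warning
  (self-similarity is 1 by definition), asymmetry beyond 10⁻⁹ is an error.
* Similarity matrices are exactly symmetrized and clipped to [0, 1] on
  construction; ties everywhere break toward the lowest index.
* The partitioner is a heuristic: optimality is guaranteed nowhere, only
  measured (see above).  Very small parts below the balance floor fall
  back to a plain halving of the Fiedler order.
* The spectral step uses a dense symmetric eigensolver up to n = 1500 and
  a deterministic shift-invert Lanczos beyond.
* k-medoids and k-means are restart heuristics; determinism holds for a
  fixed seed, global optimality is not claimed.
* Flexible-beta UPGMA with `beta > 0` can produce dendrogram inversions;
  cut labels remain well defined (first `n − k` merges) but heights are
  not monotone.
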