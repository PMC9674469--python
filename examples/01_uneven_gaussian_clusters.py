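"""Graph-theoretic clustering vs k-means on uneven Gaussian clusters.

Six bivariate normal clusters with very uneven sizes (20..500 points) are a
classic failure case for centroid-based clustering: splitting a dense
cluster saves more within-cluster variance than keeping a sparse cluster
separate, so k-means merges small clusters and splits big ones.  The
graph-based algorithm partitions a k-nearest-neighbor graph and is
insensitive to density differences.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import interclust as ic

cfg = ic.gaussian_preset("fig1_ii", seed=0)  # sizes 20, 100, 500, 20, 100, 500
points, truth = ic.simulate_gaussian_clusters(cfg)
sim = ic.points_to_similarity(points)

cham = ic.chameleon_cluster(sim, k_neighbors=15, k_final=6)
km = ic.kmeans_points(points, k=6, seed=0, n_restarts=25)

print(f"n = {len(points)} points in 6 clusters of sizes {cfg.sizes}")
print(f"graph clustering ARI vs truth: {adjusted_rand_score(truth, cham.labels):.3f}")
print(f"k-means (25 restarts) ARI vs truth: {adjusted_rand_score(truth, km.labels):.3f}")
print("ARI 1.0 means the generating clusters were recovered exactly;")
print("k-means typically scores ~0.8 here because it splits a 500-point")
print("cluster while merging a 20-point cluster into a neighbor.")
print("k-means cluster sizes:", sorted(km.cluster_sizes().values()))
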