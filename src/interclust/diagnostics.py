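"""Diagnostic-species scoring and comparison with a reference typology.

Two fidelity criteria per (species, cluster) pair on a binary plot matrix:

* hypergeometric concentration — the lower-tail probability ``P(H < x)``
  with ``H ~ Hypergeometric(N, X, m)`` where ``N`` is the number of plots,
  ``X`` the species' total occurrences, ``m`` the cluster size and ``x``
  its occurrences inside the cluster.  A species is diagnostic when this
  probability exceeds a threshold (default 0.999), i.e. the in-cluster
  frequency is statistically higher than the background.
* standardized phi — the 2x2 association coefficient between cluster
  membership and species presence, recomputed after rescaling the target
  cluster to equal relative size ``1/k`` so fidelity is comparable across
  clusters of different sizes.

No multiple-testing correction is applied by default (raw thresholds are
the field convention for this use); pass ``bonferroni=True`` to divide the
implied alpha by the number of (species, cluster) tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import CommunityMatrix, ReferenceClassification

__all__ = [
    "hypergeometric_diagnostics",
    "phi_diagnostics",
    "diagnostic_counts",
    "reference_confusion",
]


def _counts(m: CommunityMatrix, labels: np.ndarray):
    if not m.is_binary:
        raise ValueError("diagnostics require a presence-absence matrix")
    labels = np.asarray(labels, dtype=int)
    if len(labels) != m.n_plots:
        raise ValueError("labels length must match the number of plots")
    clusters = np.unique(labels)
    N = m.n_plots
    X = m.values.sum(axis=0)  # per-species totals
    rows = []
    for c in clusters:
        mask = labels == c
        mm = int(mask.sum())
        x = m.values[mask].sum(axis=0)
        rows.append((int(c), mm, x))
    return clusters, N, X, rows


def hypergeometric_diagnostics(
    m: CommunityMatrix,
    labels,
    p_threshold: float = 0.999,
    strict_tail: bool = True,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Lower-tail hypergeometric probability per (species, cluster).

    ``strict_tail=True`` uses ``P(H < x)`` (so exceeding 0.999 is an
    upper-tail test at level 0.001); ``False`` uses ``P(H <= x)``.
    """
    clusters, N, X, per_cluster = _counts(m, labels)
    recs = []
    for c, mm, x in per_cluster:
        # P(H < x) = cdf(x - 1); P(H <= x) = cdf(x)
        shift = 1 if strict_tail else 0
        p = hypergeom.cdf(x - shift, N, X.astype(int), mm)
        for j, sp in enumerate(m.species_ids):
            recs.append(
                dict(species_id=sp, cluster_id=c, x=int(x[j]), m=mm,
                     X=int(X[j]), N=N,
                     in_cluster_frequency=x[j] / mm,
                     hypergeom_p=float(p[j]))
            )
    table = pd.DataFrame(recs)
    thr = p_threshold
    if bonferroni:
        alpha = (1 - p_threshold) / len(table)
        thr = 1 - alpha
    table["diag_hypergeom"] = table["hypergeom_p"] > thr
    return table


def _phi(N: float, m: float, X: float, x: float) -> float:
    denom = m * X * (N - m) * (N - X)
    if denom <= 0:
        return 0.0  # species everywhere or nowhere: no association defined
    return float((N * x - m * X) / np.sqrt(denom))


def phi_diagnostics(
    m: CommunityMatrix,
    labels,
    phi_threshold: float = 0.35,
    standardize_to_equal_sizes: bool = True,
    target_size: float | None = None,
) -> pd.DataFrame:
    """(Standardized) phi coefficient per (species, cluster).

    Standardization rescales the target cluster to relative size
    ``target_size`` (default ``1/k``) while preserving the in-cluster and
    out-of-cluster relative frequencies, making fidelity values comparable
    across clusters.  The flag column uses ``phi >= phi_threshold``.
    """
    clusters, N, X, per_cluster = _counts(m, labels)
    if len(clusters) < 2:
        raise ValueError("phi requires at least 2 clusters")
    k = len(clusters)
    size = target_size if target_size is not None else 1.0 / k
    recs = []
    for c, mm, x in per_cluster:
        for j, sp in enumerate(m.species_ids):
            if standardize_to_equal_sizes:
                p_in = x[j] / mm
                p_out = (X[j] - x[j]) / (N - mm) if N > mm else 0.0
                m_s = size * N
                x_s = p_in * m_s
                X_s = x_s + p_out * (N - m_s)
                phi = _phi(N, m_s, X_s, x_s)
            else:
                phi = _phi(N, mm, X[j], x[j])
            recs.append(
                dict(species_id=sp, cluster_id=c, x=int(x[j]), m=mm,
                     X=int(X[j]), N=N,
                     in_cluster_frequency=x[j] / mm, phi=phi)
            )
    table = pd.DataFrame(recs)
    table["diag_phi"] = table["phi"] >= phi_threshold
    return table


def diagnostic_counts(
    table: pd.DataFrame,
    freq_threshold: float = 0.3,
    unique_species: bool = False,
) -> dict:
    """Per-solution totals of diagnostic flags.

    Counts (species, cluster) pairs by default, or unique species with
    ``unique_species=True``.  For each flag column present, also reports the
    joint count with in-cluster frequency >= ``freq_threshold`` and the
    median in-cluster frequency of those joint passers (None when empty).
    """
    if table.empty:
        raise ValueError("diagnostic table is empty")
    out: dict = {}
    for flag in ("diag_hypergeom", "diag_phi"):
        if flag not in table.columns:
            continue
        passed = table[table[flag]]
        joint = passed[passed["in_cluster_frequency"] >= freq_threshold]
        if unique_species:
            out[f"n_{flag}"] = int(passed["species_id"].nunique())
            out[f"n_{flag}_freq"] = int(joint["species_id"].nunique())
        else:
            out[f"n_{flag}"] = int(len(passed))
            out[f"n_{flag}_freq"] = int(len(joint))
        out[f"median_freq_{flag}"] = (
            float(joint["in_cluster_frequency"].median()) if len(joint) else None
        )
    return out


def reference_confusion(
    diag: pd.DataFrame,
    ref: ReferenceClassification,
    flag: str = "diag_hypergeom",
) -> pd.DataFrame:
    """Reference-class x cluster confusion matrix.

    Entry (class, cluster) is the proportion of the reference class's
    indicative species identified as diagnostic of the cluster.  Row order
    follows the reference; column order follows sorted cluster ids.
    """
    if flag not in diag.columns:
        raise ValueError(f"diagnostic table has no flag column {flag!r}")
    clusters = sorted(diag["cluster_id"].unique())
    diag_sets = {
        c: set(diag.loc[(diag["cluster_id"] == c) & diag[flag], "species_id"])
        for c in clusters
    }
    rows = {}
    for cls in ref.class_order:
        species = ref.classes[cls]
        if not species:
            raise ValueError(f"reference class {cls!r} is empty")
        rows[cls] = [len(species & diag_sets[c]) / len(species) for c in clusters]
    return pd.DataFrame.from_dict(rows, orient="index", columns=clusters)
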