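"""Presence-absence transformation and Sørensen (Bray-Curtis) similarity.

Cover-abundance community data are binarized before clustering to remove
observer bias in abundance estimates; pairwise compositional similarity is
then the Sørensen(-Dice) index ``2a / (2a + b + c)`` where ``a`` counts
species shared by the two plots and ``b``, ``c`` the species unique to each.
On binary data this equals ``1 - Bray-Curtis dissimilarity``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import CommunityMatrix, SimilarityMatrix, warn

__all__ = ["to_presence_absence", "bray_curtis_similarity"]


def to_presence_absence(m: CommunityMatrix) -> CommunityMatrix:
    """Binarize abundances: entry is 1 iff the input entry is positive.

    Idempotent; all-zero plots survive the transform (downstream similarity
    rejects them).
    """
    out = CommunityMatrix(
        plot_ids=list(m.plot_ids),
        species_ids=list(m.species_ids),
        values=(m.values > 0).astype(float),
    )
    if out.empty_plots():
        warn(f"plots with no species after binarization: {out.empty_plots()[:5]}")
    return out


def bray_curtis_similarity(m: CommunityMatrix) -> SimilarityMatrix:
    """Pairwise Sørensen similarity between plots of a binary matrix.

    Raises if the matrix is not binary or any plot has zero species
    (similarity is undefined for an empty plot).  Species occurring in no
    plot are dropped with a warning first — they cannot change any pairwise
    score but would distort frequency-based diagnostics.
    """
    if not m.is_binary:
        raise ValueError("similarity requires a presence-absence matrix; "
                         "apply to_presence_absence first")
    empty = m.empty_plots()
    if empty:
        raise ValueError(f"similarity undefined for plots with zero species: {empty[:5]}")
    x = m.values
    unseen = ~np.any(x > 0, axis=0)
    if np.any(unseen):
        dropped = [s for s, u in zip(m.species_ids, unseen) if u]
        warn(f"dropping {len(dropped)} species observed in zero plots: {dropped[:5]}")
        x = x[:, ~unseen]
    if x.shape[0] == 1:
        values = np.ones((1, 1))
    else:
        # Bray-Curtis on 0/1 data is (b + c) / (2a + b + c); Sørensen = 1 - that
        values = 1.0 - squareform(pdist(x, metric="braycurtis"))
        np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(sample_ids=list(m.plot_ids), values=values)
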