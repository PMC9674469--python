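import numpy as np
import pytest

from interclust.datatypes import CommunityMatrix, SimilarityMatrix


def random_similarity(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    """Random valid similarity matrix (symmetric, unit diagonal, [0,1])."""
    a = rng.random((n, n))
    s = (a + a.T) / 2
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(sample_ids=[str(i) for i in range(n)], values=s)


def random_binary_community(
    n_plots: int, n_species: int, rng: np.random.Generator, p: float = 0.4
) -> CommunityMatrix:
    """Random presence-absence matrix with every plot and species nonempty."""
    while True:
        values = (rng.random((n_plots, n_species)) < p).astype(float)
        if values.sum(axis=1).min() > 0 and values.sum(axis=0).min() > 0:
            return CommunityMatrix(
                plot_ids=[f"p{i}" for i in range(n_plots)],
                species_ids=[f"s{j}" for j in range(n_species)],
                values=values,
            )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim(rng):
    return random_similarity(10, rng)
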