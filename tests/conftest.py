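import numpy as np
import pytest
from hypothesis import settings

from scspac import CountMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes × 2 cells with the literal entries {{0,1},{2,0},{5,3}}."""
    return CountMatrix(
        np.array([[0, 1], [2, 0], [5, 3]]),
        ["g1", "g2", "g3"],
        ["c1", "c2"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_count_matrix(rng: np.random.Generator, n_genes: int, n_cells: int) -> CountMatrix:
    counts = rng.poisson(2.0, size=(n_genes, n_cells))
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
    )
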