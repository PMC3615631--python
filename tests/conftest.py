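import numpy as np
import pytest

from omimwalk import AssociationSet, SimilarityMatrix


def random_similarity(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    """Random symmetric similarity matrix with unit diagonal."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = tuple(f"{100000 + i}" for i in range(n))
    return SimilarityMatrix(ids, a)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim(rng):
    return random_similarity(10, rng)


@pytest.fixture
def chain_sim():
    """Three diseases a-b-c in a path: a and c only reachable through b."""
    vals = np.array(
        [
            [1.0, 0.5, 0.0],
            [0.5, 1.0, 0.3],
            [0.0, 0.3, 1.0],
        ]
    )
    return SimilarityMatrix(("100001", "100002", "100003"), vals)


@pytest.fixture
def two_pair_assoc():
    return AssociationSet(
        frozenset({("hsa-let-7g", "114480"), ("hsa-let-7g", "155720")})
    )
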