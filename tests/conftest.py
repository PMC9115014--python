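import numpy as np
import pytest

from lmdh.seq_distance import DistanceMatrix
from lmdh.structure import HaplotypeFrequencyTable


def random_distance_matrix(rng: np.random.Generator, n: int, scale: float = 0.2) -> DistanceMatrix:
    """Random symmetric non-negative matrix with zero diagonal."""
    d = rng.uniform(0.0, scale, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    labels = [f"t{i:02d}" for i in range(n)]
    return DistanceMatrix(labels=labels, d=d, sites=np.full((n, n), 100), model="K2P")


def random_hap_table(rng: np.random.Generator, K: int | None = None, H: int | None = None):
    """Random haplotype frequency table with n_k >= 2 everywhere."""
    K = K or int(rng.integers(2, 5))
    H = H or int(rng.integers(3, 7))
    counts = rng.integers(0, 8, size=(K, H))
    counts[:, 0] += 2
    return HaplotypeFrequencyTable(
        haplotypes=[f"h{i}" for i in range(H)],
        sequences=["A" * 10] * H,
        populations=[f"p{k}" for k in range(K)],
        counts=counts,
    )


def random_delta(rng: np.random.Generator, H: int, scale: float = 0.2) -> np.ndarray:
    delta = rng.uniform(0.01, scale, size=(H, H))
    delta = (delta + delta.T) / 2.0
    np.fill_diagonal(delta, 0.0)
    return delta


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
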