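import numpy as np
import pytest

from nucleoform.binning import bin_genome
from nucleoform.contacts import matrix_from_triplets


@pytest.fixture
def two_chrom_binning():
    return bin_genome({"chr1": 50_000, "chr2": 30_000}, 10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_raw_matrix(binning, rng, density=0.6, max_count=20):
    """Random sparse symmetric raw matrix with strictly positive marginals."""
    n = binning.n_bins
    dense = rng.integers(0, max_count, size=(n, n))
    dense[rng.random((n, n)) > density] = 0
    dense = np.triu(dense)
    # guarantee positive marginals: connect each bin to its successor
    for i in range(n - 1):
        if dense[i, i + 1] == 0:
            dense[i, i + 1] = 1
    rows, cols = np.nonzero(dense)
    return matrix_from_triplets(binning, rows, cols, dense[rows, cols])
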