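import numpy as np
import pytest
import scipy.sparse as sp

from isoniche import CountMatrix, build_hex_lattice, build_neighbor_graph


@pytest.fixture
def small_lattice():
    """6 x 12 staggered grid: 36 spots, interior spots have 6 neighbors."""
    return build_hex_lattice(6, 12)


@pytest.fixture
def small_graph(small_lattice):
    return build_neighbor_graph(small_lattice)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(counts, spots=None, features=None, level="gene", iso2gene=None):
    counts = np.asarray(counts)
    n_s, n_f = counts.shape
    spots = spots or [f"s{i}" for i in range(n_s)]
    features = features or [f"f{j}" for j in range(n_f)]
    return CountMatrix(spots=spots, features=features, counts=sp.csr_matrix(counts),
                       level=level, iso2gene=iso2gene)


@pytest.fixture
def make_count_matrix():
    return make_matrix
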