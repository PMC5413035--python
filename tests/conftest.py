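import numpy as np
import pytest

from resispread.core import GenotypeTable, PairwiseMatrix, RasterGrid
from resispread.resistance import ResistanceSurface


def uniform_surface(n_rows, n_cols, value=1.0, cell_size=100.0):
    grid = RasterGrid(np.full((n_rows, n_cols), float(value)), cell_size)
    return ResistanceSurface(grid)


def surface_from_values(values, cell_size=100.0):
    return ResistanceSurface(RasterGrid(np.asarray(values, dtype=float), cell_size))


def random_genotype_table(n, n_loci=10, alleles=6, seed=0, extent=1000.0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, extent, size=(n, 2))
    genotypes = 100 + 2 * rng.integers(0, alleles, size=(n, n_loci, 2))
    return GenotypeTable(
        ids=[f"i{k}" for k in range(n)], coordinates=coords, genotypes=genotypes
    )


def square_matrix(values, kind, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = list(range(values.shape[0]))
    return PairwiseMatrix(ids=ids, values=values, metric_kind=kind)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
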