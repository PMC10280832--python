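import numpy as np
import pytest
import scipy.sparse as sp

from schptm_bench import (
    BinScheme,
    CountMatrix,
    GenomeLayout,
    SimulationConfig,
    make_fixed_bins,
    simulate_paired_dataset,
)


def dense_to_cm(dense, bin_size=100, barcodes=None, layout=None):
    """CountMatrix from a dense array; columns become fixed-size bins on one
    toy chromosome."""
    dense = np.asarray(dense)
    n_cells, n_regions = dense.shape
    if layout is None:
        layout = GenomeLayout(("chr1",), (n_regions * bin_size,))
    scheme = make_fixed_bins(layout, bin_size)
    if barcodes is None:
        barcodes = np.array([f"BC{i:04d}" for i in range(n_cells)], dtype=object)
    return CountMatrix(sp.csr_matrix(dense), barcodes, scheme)


@pytest.fixture
def cm_factory():
    return dense_to_cm


@pytest.fixture(scope="session")
def small_dataset():
    """300-cell paired dataset with default (broad-mark) signal."""
    config = SimulationConfig(n_cells=300, rna_n_genes=400, rna_mean_depth=2000, seed=123)
    return simulate_paired_dataset(config)
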