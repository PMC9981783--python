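import numpy as np
import pytest
import scipy.sparse as sp

from atacfuse import Peak, PeakCountMatrix
from atacfuse.synthetic import SyntheticDesign, simulate_scatac


def make_pm(counts, chrom="chr1") -> PeakCountMatrix:
    """Wrap a dense array as a PeakCountMatrix with synthetic coordinates."""
    counts = np.asarray(counts)
    peaks = [Peak(chrom, i * 1000, i * 1000 + 500) for i in range(counts.shape[0])]
    barcodes = [f"cell{i}" for i in range(counts.shape[1])]
    return PeakCountMatrix(counts=sp.csr_matrix(counts), peaks=peaks, barcodes=barcodes)


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    return SyntheticDesign(
        n_cells=120, n_peaks=600, n_genes=12, n_motifs=8, n_types=4,
        depth_mean=800.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """A modest 4-type synthetic dataset shared across tests (read-only)."""
    return simulate_scatac(small_design)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
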