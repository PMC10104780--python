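import numpy as np
import pandas as pd
import pytest

from dsb3d.io import BinTable, ContactMatrix


@pytest.fixture
def small_bins():
    """Two tiny chromosomes at 10-kb bins (chr1: 6 bins, chr2: 4 bins)."""
    return BinTable.from_chromsizes({"chr1": 60_000, "chr2": 40_000}, 10_000)


def random_matrix(bins: BinTable, seed: int = 0, density: float = 1.0,
                  max_count: int = 50) -> ContactMatrix:
    """Dense-ish random symmetric contact matrix on a bin table."""
    rng = np.random.default_rng(seed)
    n = len(bins)
    rows = []
    for chrom in bins.chromosomes:
        sl = bins.chrom_slice(chrom)
        for i in range(sl.start, sl.stop):
            for j in range(i, sl.stop):
                if rng.random() < density:
                    rows.append((i, j, int(rng.integers(1, max_count))))
    return ContactMatrix(bins, pd.DataFrame(rows, columns=["bin1_id", "bin2_id", "count"]))


@pytest.fixture
def random_small_matrix(small_bins):
    return random_matrix(small_bins, seed=3)


def dense_to_matrix(dense: np.ndarray, bin_size: int = 10_000,
                    chrom: str = "chr1") -> ContactMatrix:
    """Wrap a symmetric dense array as a single-chromosome ContactMatrix."""
    n = dense.shape[0]
    bins = BinTable.from_chromsizes({chrom: n * bin_size}, bin_size)
    iu, ju = np.triu_indices(n)
    counts = np.asarray(dense, dtype=np.int64)[iu, ju]
    nz = counts > 0
    px = pd.DataFrame({"bin1_id": iu[nz], "bin2_id": ju[nz], "count": counts[nz]})
    return ContactMatrix(bins, px)


def uniform_oe(n: int, bin_size: int, chrom: str = "chr1", value: float = 1.0):
    """An OEMaps with a constant O/E matrix on one chromosome."""
    from dsb3d.matrix import OEMaps

    bins = BinTable.from_chromsizes({chrom: n * bin_size}, bin_size)
    return OEMaps(bins, {chrom: np.full((n, n), value)})
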