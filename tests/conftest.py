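import numpy as np
import pytest

from sweepscan.io import GenotypeMatrix
from sweepscan.simulate import SimConfig, simulate_genotypes


def make_matrix(dosage, pos=None, chrom="chr1", sample_ids=None, **kw):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        dosage=dosage,
        **kw,
    )


def central_common_snp(matrix, maf_min=0.2):
    """Index of the SNP nearest the middle of the matrix with MAF >= maf_min.

    Power checks plant the causal effect on a common variant: a
    near-monomorphic SNP carries no marginal signal whatever its effect
    size, so frequency is part of the planted-effect design."""
    g = matrix.dosage.astype(float)
    called = g >= 0
    p = np.where(called, g, 0).sum(axis=0) / (2 * called.sum(axis=0))
    maf = np.minimum(p, 1 - p)
    ok = np.flatnonzero(maf >= maf_min)
    return int(ok[np.argmin(np.abs(ok - matrix.n_variants // 2))])


@pytest.fixture(scope="session")
def default_panel():
    """Default 19-sample two-chromosome panel with the planted sweep."""
    cfg = SimConfig(seed=0)
    matrix, table = simulate_genotypes(cfg)
    return cfg, matrix, table


@pytest.fixture(scope="session")
def neutral_panel():
    """Sweep-free single-chromosome 19-sample panel."""
    cfg = SimConfig(seed=7, n_chrom=1, chrom_length=1_000_000, sweep_intervals=[])
    matrix, table = simulate_genotypes(cfg)
    return cfg, matrix, table
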