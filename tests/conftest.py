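import numpy as np
import pytest

from steppekin import synthetic_data as sd
from steppekin.io_formats import GenotypeTable, SnpMeta


@pytest.fixture(scope="session")
def small_panel():
    """500 SNPs on 8 chromosomes (~1,200 cM): fast gene-drop substrate."""
    return sd.make_snp_panel(n_snps=500, n_chrom=8, total_cM=1200.0, seed=11)


@pytest.fixture(scope="session")
def dense_panel():
    """Physically dense panel (1 SNP / ~120 kb) for ROH calling tests."""
    return sd.make_snp_panel(
        n_snps=5000, n_chrom=6, total_cM=600.0, bp_per_cM=1e6, seed=12
    )


@pytest.fixture
def tiny_table():
    """3 samples x 5 SNPs with one missing call."""
    snps = [
        SnpMeta(f"s{j}", chrom=1, pos_bp=1000 * (j + 1), pos_cM=0.1 * j,
                alleles=("A", "G"), freq_alt=0.4)
        for j in range(5)
    ]
    calls = np.array(
        [[0, 1, 2, 0, 1],
         [2, 2, 0, 1, 0],
         [1, 0, 1, -1, 2]], dtype=np.int8
    )
    return GenotypeTable(samples=["i1", "i2", "i3"], snps=snps, calls=calls)
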