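import numpy as np
import pandas as pd
import pytest

from regelex import synthio


@pytest.fixture(scope="session")
def small_panel():
    """50-SNP panel used by LD oracle tests."""
    return synthio.simulate_haplotype_panel(
        100, n_blocks=5, snps_per_block=10, seed=101
    )


@pytest.fixture(scope="session")
def medium_panel():
    """Multi-block panel for fine-mapping and LD-score tests."""
    return synthio.simulate_haplotype_panel(
        200, n_blocks=20, snps_per_block=20, seed=102
    )


def two_snp_panel(counts):
    """Panel with two SNPs built from a dict of haplotype-pair counts,
    e.g. {(1, 1): 3, (1, 0): 1, (0, 1): 1, (0, 0): 3}."""
    rows = []
    for (a, b), k in counts.items():
        rows.extend([[a, b]] * k)
    hap = np.array(rows, dtype=np.int8)
    meta = pd.DataFrame(
        {
            "variant_id": ["snpA", "snpB"],
            "chrom": ["chrS", "chrS"],
            "pos": [100, 200],
            "ref": ["A", "A"],
            "alt": ["C", "C"],
            "block": [0, 0],
        }
    )
    return synthio.HaplotypePanel(hap, meta)
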