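import numpy as np
import pandas as pd
import pytest

from snp2tf.containers import GenotypeMatrix
from snp2tf.simulate import SimConfig, simulate_genotypes, simulate_phenotype


def make_genotypes(codes, chrom="1", start_pos=1000, spacing=1000):
    """GenotypeMatrix from a raw code matrix (rows = animals)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": [start_pos + spacing * j for j in range(m)],
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(
        animal_ids=[f"a{i}" for i in range(n)], snps=snps, codes=codes
    )


@pytest.fixture(scope="session")
def additive_cohort():
    """500 animals x 100 SNPs, 5 strong additive QTL, h2 = 0.5."""
    cfg = SimConfig(
        n_animals=500, n_snps=100, maf_range=(0.1, 0.5), missing_rate=0.0,
        n_additive=5, n_epistatic_pairs=0, additive_effect=1.0,
        heritability=0.5, seed=42,
    )
    G = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(G, cfg)
    return G, y, truth
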