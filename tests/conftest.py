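import numpy as np
import pandas as pd
import pytest

from snpherit import GenotypeMatrix, SimConfig, simulate_cohort


def make_geno(dosages, chrom=None, pos=None, a1="A", a2="G", maf=None):
    """Build a GenotypeMatrix from a raw dosage array for tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    if pos is None:
        pos = np.concatenate(
            [np.arange(1, (chrom == c).sum() + 1) * 1000
             for c in pd.unique(chrom)]
        )
    meta = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": a1,
            "a2": a2,
            "maf": np.nan if maf is None else maf,
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"f{i}" for i in range(n)], "iid": [f"i{i}" for i in range(n)]}
    )
    return GenotypeMatrix(d, meta, samples)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest parental-mode cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_individuals=400, n_snps=600,
                                     n_causal_shared=150, seed=11))
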