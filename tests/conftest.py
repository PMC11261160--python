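import numpy as np
import pandas as pd
import pytest

from ldne.matrix import GenotypeMatrix


def as_matrix(g, chrom=None, population="pop1", cohort="cohort1"):
    """Wrap a plain allele-count array in a GenotypeMatrix."""
    g = np.asarray(g)
    n, L = g.shape
    if chrom is None:
        chrom = ["chr1"] * L
    locus_meta = pd.DataFrame(
        {"id": [f"snp{j}" for j in range(L)], "chrom": chrom, "pos": np.arange(1, L + 1)}
    )
    indiv_meta = pd.DataFrame(
        {"id": [f"ind{i}" for i in range(n)], "population": population, "cohort": cohort}
    )
    return GenotypeMatrix(g, locus_meta, indiv_meta)


def hwe_genotypes(rng, n, p):
    """HWE genotypes for loci with allele frequencies ``p`` (len L)."""
    p = np.atleast_1d(p)
    return (
        (rng.random((n, p.size)) < p).astype(np.int8)
        + (rng.random((n, p.size)) < p).astype(np.int8)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """20 individuals x 30 loci in HWE with a few missing calls."""
    p = rng.uniform(0.1, 0.9, 30)
    g = hwe_genotypes(rng, 20, p)
    miss = rng.random(g.shape) < 0.05
    g[miss] = -1
    return as_matrix(g)
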