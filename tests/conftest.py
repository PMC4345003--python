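import numpy as np
import pytest

from epiqtl.datatypes import GenotypeMatrix, SnpMeta


def make_genotypes(values, chrom="1", positions=None, snp_prefix="s"):
    """GenotypeMatrix from a plain array with synthetic metadata."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(m)]
    if isinstance(chrom, str):
        chrom = [chrom] * m
    snps = [
        SnpMeta(f"{snp_prefix}{j}", chrom[j], positions[j], "A", "G")
        for j in range(m)
    ]
    return GenotypeMatrix(values, [f"i{i}" for i in range(n)], snps)


def random_dosages(rng, n, maf):
    return (rng.random(n) < maf).astype(float) + (rng.random(n) < maf)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """60 individuals x 6 SNPs on two chromosomes, no missing data."""
    rng = np.random.default_rng(7)
    values = np.column_stack([random_dosages(rng, 60, 0.4) for _ in range(6)])
    return make_genotypes(
        values,
        chrom=["1", "1", "1", "2", "2", "2"],
        positions=[100_000, 300_000, 5_000_000, 100_000, 200_000, 9_000_000],
    )
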