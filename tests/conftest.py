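import numpy as np
import pytest

from epipair.datatypes import GenotypeDataset, snp_frame


def make_dataset(dosage, phenotype, chrom=None, pos=None, alleles=None,
                 ids=None) -> GenotypeDataset:
    """Small literal dataset from a dosage matrix."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = chrom or ["1"] * m
    pos = pos or list(range(1, m + 1))
    alleles = alleles or [("A", "G")] * m
    ids = ids or [f"rs{j + 1}" for j in range(m)]
    snps = snp_frame([
        (ids[j], chrom[j], pos[j], alleles[j][0], alleles[j][1])
        for j in range(m)
    ])
    return GenotypeDataset(
        snps=snps,
        sample_ids=np.array([f"S{i + 1}" for i in range(n)], dtype=object),
        dosage=dosage,
        phenotype=np.asarray(phenotype, dtype=np.int8),
    )


def random_dataset(rng, n=60, m=10, maf=(0.1, 0.5), missing=0.0,
                   balanced=True) -> GenotypeDataset:
    p = rng.uniform(*maf, size=m)
    dosage = ((rng.random((n, m)) < p).astype(np.int8)
              + (rng.random((n, m)) < p).astype(np.int8))
    if missing > 0:
        dosage = np.where(rng.random((n, m)) < missing, np.int8(-1), dosage)
    if balanced:
        phen = np.array([1] * (n // 2) + [0] * (n - n // 2), dtype=np.int8)
    else:
        phen = (rng.random(n) < 0.5).astype(np.int8)
    return make_dataset(dosage, phen)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, n=80, m=12, missing=0.02)
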