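import numpy as np
import pytest

from epitabu.io import GenotypeTable, encode_bits


@pytest.fixture
def worked_table() -> GenotypeTable:
    """Four-sample, two-SNP table whose value-1 bitstrings are 1101 and 1001."""
    genotypes = np.array(
        [
            [1, 1],
            [1, 0],
            [0, 0],
            [1, 1],
        ]
    )
    phenotype = np.array([1, 0, 1, 0])
    return GenotypeTable(["SNPB", "SNPC"], genotypes, phenotype)


@pytest.fixture
def worked_bits(worked_table):
    return encode_bits(worked_table)


def random_table(rng: np.random.Generator, n_samples: int, n_snps: int) -> GenotypeTable:
    """Uniform random genotype table; both classes forced to appear."""
    genotypes = rng.integers(0, 3, size=(n_samples, n_snps))
    phenotype = rng.integers(0, 2, size=n_samples)
    if n_samples >= 2:
        phenotype[0], phenotype[1] = 0, 1
    return GenotypeTable(
        [f"S{i}" for i in range(n_snps)], genotypes, phenotype
    )


@pytest.fixture
def make_random_table():
    return random_table
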