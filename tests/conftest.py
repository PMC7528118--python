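import numpy as np
import pytest

from hybrisect.core import (
    GenotypePanel,
    Habit,
    Role,
    Sample,
    SnpLocus,
    genotype_from_symbols,
)


def make_samples(n_cultivars=1, outgroup=False, habits=None):
    samples = [
        Sample("AX", Role.PROGENITOR_A),
        Sample("INT", Role.PROGENITOR_B),
    ]
    if outgroup:
        samples.append(Sample("EXS", Role.OUTGROUP_SPECIES))
    habits = habits or [Habit.TRAILING] * n_cultivars
    samples += [Sample(f"c{i+1}", Role.CULTIVAR, habits[i]) for i in range(n_cultivars)]
    return samples


def build_panel(loci, samples, genotypes, depths=None):
    """Panel from symbolic genotypes: genotypes[i][j] is an allele pair or None."""
    calls = np.full((len(loci), len(samples), 2), -1, dtype=np.int8)
    for i, locus in enumerate(loci):
        for j, gt in enumerate(genotypes[i]):
            calls[i, j] = genotype_from_symbols(gt, locus)
    return GenotypePanel(loci=list(loci), samples=list(samples), calls=calls, depths=depths)


@pytest.fixture
def biallelic_locus():
    return SnpLocus("t1", 10, "A", ("G",))


@pytest.fixture
def triallelic_locus():
    return SnpLocus("t1", 10, "A", ("G", "T"))


def random_panel(rng, n_loci=20, n_cultivars=3, missing_rate=0.1, n_alleles=3):
    """Small random panel over a fixed allele universe, for property tests."""
    alleles = "ACGT"[:n_alleles]
    loci = [SnpLocus(f"t{i // 4}", 1 + i % 4 * 7, alleles[0], tuple(alleles[1:])) for i in range(n_loci)]
    samples = make_samples(n_cultivars=n_cultivars)
    calls = rng.integers(0, n_alleles, size=(n_loci, len(samples), 2)).astype(np.int8)
    miss = rng.random((n_loci, len(samples))) < missing_rate
    calls[miss] = -1
    return GenotypePanel(loci=loci, samples=samples, calls=calls)
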