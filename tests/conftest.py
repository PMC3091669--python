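import numpy as np
import pandas as pd
import pytest

from asepool import SimulationConfig, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20100813)


@pytest.fixture
def small_config():
    return SimulationConfig(seed=11, n_genes=40, n_animals=100)


@pytest.fixture
def random_snps(rng):
    """50 random non-duplicate SNP records across two chromosomes."""
    pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
    positions = rng.choice(np.arange(1, 10_000), size=50, replace=False)
    out = []
    for i, pos in enumerate(sorted(positions)):
        ref, alt = pairs[rng.integers(0, len(pairs))]
        out.append(SnpRecord("chr1" if i % 2 else "chr2", int(pos), ref, alt))
    return out


def make_observations(snp, n_ref, n_alt, n_other=0, strand="+", qual=30,
                      unique=True, prefix="r"):
    """Hand-built observations over one SNP: n_ref ref-base reads, n_alt
    alt-base reads, n_other reads with a base matching neither allele."""
    from asepool import ReadObservation

    other = next(b for b in "ACGTN"
                 if b not in (snp.ref_allele, snp.alt_allele))
    obs = []
    for i in range(n_ref):
        obs.append(ReadObservation(f"{prefix}ref{i}", snp.chrom, snp.pos, strand,
                                   snp.ref_allele, qual, unique))
    for i in range(n_alt):
        obs.append(ReadObservation(f"{prefix}alt{i}", snp.chrom, snp.pos, strand,
                                   snp.alt_allele, qual, unique))
    for i in range(n_other):
        obs.append(ReadObservation(f"{prefix}oth{i}", snp.chrom, snp.pos, strand,
                                   other, qual, unique))
    return obs
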