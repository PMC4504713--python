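import numpy as np
import pytest

from radmap.config import SimConfig
from radmap.sim import QTL, simulate_experiment

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@pytest.fixture(scope="session")
def small_truth():
    """Two-chromosome error-free experiment, every locus polymorphic."""
    cfg = SimConfig(n_chromosomes=2, chrom_length_cM=120.0, n_sites=40,
                    snp_fraction=1.0, n_lines=94, coverage_mean=8.0, seed=101)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def qtl_truth():
    """Seven-chromosome experiment with one additive QTL at the design
    point: a = 8.9, sigma chosen so the expected PVE is 44.5%."""
    cfg = SimConfig(n_chromosomes=7, chrom_length_cM=150.0, n_sites=30,
                    snp_fraction=1.0, n_lines=94, seed=77)
    return simulate_experiment(cfg, qtl=[QTL(chrom=2, pos_cM=105.5, effect=8.9)],
                               pheno_mu=71.0, pheno_sigma=9.9391)


def random_tags(rng, n, length=92):
    """Distinct random ACGT tags as sorted strings."""
    seen = set()
    while len(seen) < n:
        seen.add(bytes(BASES[rng.integers(0, 4, length)]).decode())
    return sorted(seen)


def mutate(tag, positions, rng):
    s = list(tag)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)
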