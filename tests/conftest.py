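import numpy as np
import pytest

from isopop.genotype_io import GenotypeMatrix, SampleMeta, SnpMeta
from isopop.synthetic_data import SimConfig, simulate_two_populations


@pytest.fixture(scope="session")
def diverged_cohort():
    """Two cohorts of 500 at Balding-Nichols divergence 0.003, 50k independent SNPs."""
    cfg = SimConfig(
        seed=101, n_pop1=500, n_pop2=500, n_snps=50_000,
        divergence_fst=0.003, ld_decay_bp=0,
    )
    g, truth = simulate_two_populations(cfg)
    return g, truth


@pytest.fixture(scope="session")
def null_cohort():
    """One homogeneous HWE population (the second cohort is a token)."""
    cfg = SimConfig(
        seed=202, n_pop1=200, n_pop2=2, n_snps=20_000,
        divergence_fst=0.0, ld_decay_bp=0,
    )
    g, truth = simulate_two_populations(cfg)
    return g.subset_samples(g.samples_by_population("pop1")), truth


def make_matrix(calls, positions=None, chrom="1", populations=None):
    """Small literal GenotypeMatrix for hand-traced tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    snps = [SnpMeta(f"s{j}", chrom, int(positions[j])) for j in range(m)]
    pops = populations or ["pop1"] * n
    samples = [SampleMeta(f"i{i}", population=pops[i]) for i in range(n)]
    return GenotypeMatrix(samples, snps, calls)
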