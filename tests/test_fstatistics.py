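import numpy as np
import pytest

from isopop.fstatistics import fis, fst, jackknife_se
from isopop.genotype_io import GenotypeMatrix, SampleMeta, SnpMeta
from isopop.synthetic_data import SimConfig, simulate_two_populations

from conftest import make_matrix


def _wc_components_oracle(counts_by_pop):
    """Per-SNP Weir-Cockerham (a, b, c) for two alleles, coded independently.

    ``counts_by_pop``: list of (n_AA, n_AB, n_BB) per population for one SNP.
    """
    r = len(counts_by_pop)
    n_i = np.array([sum(c) for c in counts_by_pop], dtype=float)
    p_i = np.array([(c[1] + 2 * c[2]) / (2 * sum(c)) for c in counts_by_pop])
    h_i = np.array([c[1] / sum(c) for c in counts_by_pop])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestFis:
    def test_all_heterozygous_is_minus_one(self):
        g = make_matrix(np.ones((20, 50), dtype=np.int8))
        assert fis(g, compute_se=False).estimate == pytest.approx(-1.0)

    def test_hwe_null_within_two_se(self, null_cohort):
        g, _ = null_cohort
        res = fis(g)
        assert abs(res.estimate) < 2 * res.se

    def test_selfed_offspring_raise_fis(self):
        """20% selfed offspring (F = 0.5) should push F_IS near 0.1."""
        rng = np.random.default_rng(55)
        m, n_out, n_self = 30_000, 160, 40
        p = rng.uniform(0.1, 0.5, m)
        hap = (rng.random((2 * n_out, m)) < p).astype(np.int8)
        outbred = hap[0::2] + hap[1::2]
        # selfed: both gametes copy the same parental haplotype half the time
        parents = (rng.random((2 * n_self, m)) < p).astype(np.int8)
        pick1 = rng.integers(0, 2, (n_self, m))
        pick2 = rng.integers(0, 2, (n_self, m))
        rows = np.arange(n_self)[:, None] * 2
        selfed = (
            parents[rows + pick1, np.arange(m)[None, :]]
            + parents[rows + pick2, np.arange(m)[None, :]]
        )
        g = make_matrix(np.vstack([outbred, selfed]))
        res = fis(g)
        expected = 0.2 * 0.5
        assert abs(res.estimate - expected) < 2 * res.se + 0.02


class TestFst:
    def test_random_split_of_one_pool_centers_on_zero(self):
        rng = np.random.default_rng(66)
        estimates = []
        for _ in range(50):
            p = rng.uniform(0.1, 0.5, 2000)
            calls = rng.binomial(2, p[None, :], size=(100, 2000)).astype(np.int8)
            g = make_matrix(calls, populations=["a"] * 50 + ["b"] * 50)
            estimates.append(fst(g, "a", "b", compute_se=False).estimate)
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates)) < 2 * sem

    def test_fixed_difference_is_one(self):
        calls = np.vstack([
            np.zeros((10, 30), dtype=np.int8),
            np.full((10, 30), 2, dtype=np.int8),
        ])
        g = make_matrix(calls, populations=["a"] * 10 + ["b"] * 10)
        assert fst(g, "a", "b", compute_se=False).estimate == pytest.approx(1.0)

    def test_balding_nichols_recovery_with_se_scale(self, diverged_cohort):
        g, _ = diverged_cohort
        res = fst(g, "pop1", "pop2")
        assert 0.002 <= res.estimate <= 0.004
        assert 1e-5 < res.se < 1e-3  # order of 1e-4

    @pytest.mark.parametrize("f", [0.001, 0.003, 0.01])
    def test_recovery_across_divergence_grid(self, f):
        """Mean estimate over 20 replicates within 10% of the simulated F."""
        estimates = []
        for rep in range(20):
            cfg = SimConfig(seed=1000 + rep, n_pop1=500, n_pop2=500,
                            n_snps=20_000, divergence_fst=f, ld_decay_bp=0)
            g, _ = simulate_two_populations(cfg)
            estimates.append(fst(g, "pop1", "pop2", compute_se=False).estimate)
        assert abs(np.mean(estimates) - f) <= 0.1 * f

    def test_ratio_of_sums_not_mean_of_ratios(self):
        """Combined theta equals sum(a)/sum(a+b+c) from an independent
        per-SNP component oracle, not the mean of per-SNP ratios."""
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.1, 0.9, 40)[None, :],
                             size=(30, 40)).astype(np.int8)
        g = make_matrix(calls, populations=["a"] * 15 + ["b"] * 15)
        a_sum = b_sum = c_sum = 0.0
        ratios = []
        for j in range(g.n_snps):
            per_pop = []
            for lab, sl in (("a", slice(0, 15)), ("b", slice(15, 30))):
                col = g.calls[sl, j]
                per_pop.append(((col == 0).sum(), (col == 1).sum(), (col == 2).sum()))
            a, b, c = _wc_components_oracle(per_pop)
            a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
            if a + b + c != 0:
                ratios.append(a / (a + b + c))
        expected = a_sum / (a_sum + b_sum + c_sum)
        got = fst(g, "a", "b", compute_se=False).estimate
        assert got == pytest.approx(expected, abs=1e-12)
        assert abs(got - np.mean(ratios)) > 1e-6  # the two weightings differ


class TestJackknife:
    def test_constant_statistic_has_zero_se(self, null_cohort):
        g, _ = null_cohort
        se = jackknife_se(lambda sub: 1.0, g.subset_samples(range(10)))
        assert se == 0.0

    def test_sample_mean_matches_classical_se(self):
        rng = np.random.default_rng(9)
        calls = rng.binomial(2, 0.4, size=(25, 1)).astype(np.int8)
        g = make_matrix(calls)
        se = jackknife_se(lambda sub: float(sub.calls.mean()), g)
        x = calls[:, 0].astype(float)
        classical = x.std(ddof=1) / np.sqrt(len(x))
        assert se == pytest.approx(classical, rel=1e-10)

    def test_fst_jackknife_close_to_true_sampling_sd(self):
        """Jackknife SE tracks the Monte-Carlo sampling SD of theta on a
        20+20 toy cohort (individuals re-drawn with the population allele
        frequencies held fixed) within a factor of 1.5.  Case-resampling
        bootstrap is not used as the oracle: duplicated individuals act as
        twins and genuinely inflate theta variability at this sample size.
        """
        rng = np.random.default_rng(99)
        m = 1000
        p_anc = rng.uniform(0.1, 0.5, m)
        shape = (1 - 0.01) / 0.01
        pa = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        pb = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        snps = [SnpMeta(f"s{j}", "1", j + 1) for j in range(m)]
        samples = [SampleMeta(f"i{i}", population="a" if i < 20 else "b")
                   for i in range(40)]
        ests, jacks = [], []
        for _ in range(100):
            ca = rng.binomial(2, pa[None, :], size=(20, m))
            cb = rng.binomial(2, pb[None, :], size=(20, m))
            g = GenotypeMatrix(samples, snps, np.vstack([ca, cb]).astype(np.int8))
            r = fst(g, "a", "b")
            ests.append(r.estimate)
            jacks.append(r.se)
        mc_sd = float(np.std(ests, ddof=1))
        assert mc_sd / 1.5 <= np.mean(jacks) <= mc_sd * 1.5
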