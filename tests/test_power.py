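import numpy as np
import pytest
from scipy.stats import norm

from isopop.power import (
    PowerModelSpec,
    analytic_power,
    best_proxy,
    power_distribution,
    simulate_power_mixed,
    variance_inflation,
)

from conftest import make_matrix


def _sib_block_fixture(n=400, maf=0.3, seed=3):
    """n individuals in sib pairs: duplicated genotypes, G with 0.5 blocks."""
    rng = np.random.default_rng(seed)
    G = np.eye(n)
    for i in range(0, n, 2):
        G[i, i + 1] = G[i + 1, i] = 0.5
    s = np.repeat(rng.binomial(2, maf, n // 2).astype(float), 2)
    return s, G


def _mc_power_oracle(s1, s2, v_s, alpha, reps, seed):
    """Direct OLS simulation of the uncorrelated model (independent code path)."""
    rng = np.random.default_rng(seed)
    n = s1.size
    sigma2 = np.var(s1) * (1 - v_s) / v_s
    y = s1[:, None] + np.sqrt(sigma2) * rng.standard_normal((n, reps))
    c = s2 - s2.mean()
    S = c @ c
    b = (c @ y) / S
    yc = y - y.mean(axis=0, keepdims=True)
    rss = (yc**2).sum(axis=0) - b**2 * S
    z = b / np.sqrt(rss / (n - 2) / S)
    return float(np.mean(np.abs(z) > norm.ppf(1 - alpha / 2)))


class TestBestProxy:
    def _matrix_with_duplicate(self):
        rng = np.random.default_rng(10)
        v = rng.binomial(2, 0.3, 100).astype(np.int8)
        w = rng.binomial(2, 0.3, 100).astype(np.int8)
        calls = np.stack([v, v, w], axis=1)
        return make_matrix(calls, positions=[1_000_000, 1_010_000, 1_500_000])

    def test_duplicate_nearby_wins_with_perfect_r(self):
        g = self._matrix_with_duplicate()
        proxy, r = best_proxy(g, "s0")
        assert proxy == "s1"
        assert r == pytest.approx(1.0)

    def test_everything_beyond_window_is_flagged(self):
        g = self._matrix_with_duplicate()
        proxy, r = best_proxy(g, "s0", window_bp=5_000)
        assert proxy is None and np.isnan(r)

    def test_equal_r_breaks_tie_to_closer_snp(self):
        rng = np.random.default_rng(11)
        v = rng.binomial(2, 0.3, 200).astype(np.int8)
        calls = np.stack([v, v, v], axis=1)  # both candidates have |r| = 1
        g = make_matrix(calls, positions=[1_000_000, 1_100_000, 1_050_000])
        proxy, _ = best_proxy(g, "s0")
        assert proxy == "s2"  # 50 kb beats 100 kb


class TestAnalyticPower:
    def test_null_effect_gives_alpha(self):
        rng = np.random.default_rng(12)
        s = rng.binomial(2, 0.3, 500).astype(float)
        assert analytic_power(s, s, 0.0, 1e-5) == 1e-5

    def test_orthogonal_proxy_gives_alpha(self):
        s1 = np.array([0.0, 2.0, 0.0, 2.0] * 50)
        s2 = np.array([0.0, 0.0, 2.0, 2.0] * 50)  # sample covariance 0
        assert analytic_power(s1, s2, 0.05, 1e-5) == pytest.approx(1e-5, rel=1e-6)

    @pytest.mark.parametrize("v_s,alpha", [
        (0.01, 1e-5), (0.02, 1e-5), (0.05, 1e-5),
        (0.01, 1e-7), (0.02, 1e-7), (0.05, 1e-7),
    ])
    def test_matches_monte_carlo_oracle(self, v_s, alpha):
        rng = np.random.default_rng(13)
        s = rng.binomial(2, 0.3, 977).astype(float)
        reps = 20_000
        p_mc = _mc_power_oracle(s, s, v_s, alpha, reps, seed=14)
        p_an = analytic_power(s, s, v_s, alpha)
        se = np.sqrt(max(p_mc * (1 - p_mc), 1.0 / reps) / reps)
        assert abs(p_an - p_mc) <= 3 * se

    def test_invariant_under_allele_swap_of_proxy(self):
        rng = np.random.default_rng(15)
        s1 = rng.binomial(2, 0.3, 500).astype(float)
        s2 = rng.binomial(2, 0.4, 500).astype(float)
        assert analytic_power(s1, s2, 0.02, 1e-5) == pytest.approx(
            analytic_power(s1, 2.0 - s2, 0.02, 1e-5), rel=1e-12
        )


class TestMixedModel:
    def test_minimal_heritability_reduces_to_analytic(self):
        rng = np.random.default_rng(16)
        s = rng.binomial(2, 0.3, 500).astype(float)
        G = np.eye(500)
        spec = PowerModelSpec(v_s=0.03, h2=None, alpha_grid=(1e-5,), n_reps=20_000, seed=17)
        sim = simulate_power_mixed(s, s, G, spec)[1e-5]
        ana = analytic_power(s, s, 0.03, 1e-5)
        se = np.sqrt(ana * (1 - ana) / 20_000)
        assert abs(sim - ana) <= 3 * se

    def test_identity_g_at_half_heritability_reduces_to_analytic(self):
        """With G = I the polygenic term is just extra white noise, so the
        uncorrelated formula with the same total residual variance applies."""
        rng = np.random.default_rng(18)
        s = rng.binomial(2, 0.3, 500).astype(float)
        spec = PowerModelSpec(v_s=0.03, h2=0.5, alpha_grid=(1e-5,), n_reps=20_000, seed=19)
        sim = simulate_power_mixed(s, s, np.eye(500), spec)[1e-5]
        ana = analytic_power(s, s, 0.03, 1e-5)
        se = np.sqrt(ana * (1 - ana) / 20_000)
        assert abs(sim - ana) <= 3 * se

    def test_variance_inflation_unity_for_identity_g(self):
        rng = np.random.default_rng(20)
        s = rng.binomial(2, 0.3, 200).astype(float)
        spec = PowerModelSpec(v_s=0.05, h2=0.5, n_reps=4000, seed=21)
        ratio, se = variance_inflation(s, np.eye(200), spec)
        assert abs(ratio - 1.0) <= 3 * se

    def test_variance_inflation_unity_without_polygenic_part(self):
        s, G = _sib_block_fixture()
        spec = PowerModelSpec(v_s=0.05, h2=None, n_reps=4000, seed=22)
        ratio, se = variance_inflation(s, G, spec)
        assert abs(ratio - 1.0) <= 3 * se

    def test_sib_block_inflation_matches_sandwich_oracle(self):
        """At h2 = 1, c'Gc / c'c = 1.5 exactly for duplicated sib genotypes."""
        s, G = _sib_block_fixture()
        spec = PowerModelSpec(v_s=0.05, h2=1.0, n_reps=8000, seed=23)
        ratio, se = variance_inflation(s, G, spec)
        c = s - s.mean()
        oracle = float(c @ G @ c / (c @ c))
        assert oracle == pytest.approx(1.5)
        assert ratio > 1.1
        assert abs(ratio - oracle) <= 4 * se

    def test_power_crossing_under_relatedness(self):
        """Inflated estimator variance gains power where the critical value
        exceeds the noncentrality (alpha = 1e-7 here) and loses it where it
        does not (alpha = 1e-5)."""
        s, G = _sib_block_fixture()
        n = s.size
        # choose v_s so the noncentrality sits between z(1e-5) and z(1e-7)
        target_ncp = 4.9
        v = target_ncp**2 / n
        v_s = v / (1 + v)
        spec = PowerModelSpec(v_s=v_s, h2=1.0, alpha_grid=(1e-5, 1e-7),
                              n_reps=20_000, seed=24)
        sim = simulate_power_mixed(s, s, G, spec)
        ana = {a: analytic_power(s, s, v_s, a) for a in (1e-5, 1e-7)}
        assert norm.ppf(1 - 1e-5 / 2) < target_ncp < norm.ppf(1 - 1e-7 / 2)
        assert sim[1e-7] > ana[1e-7]  # gain at the stringent threshold
        assert sim[1e-5] < ana[1e-5]  # loss at the lenient threshold

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError):
            PowerModelSpec(v_s=0.5, h2=0.2)


@pytest.fixture(scope="module")
def ld_chromosome():
    from isopop.synthetic_data import SimConfig, simulate_two_populations

    cfg = SimConfig(seed=26, n_pop1=977, n_pop2=2, n_snps=300, n_chromosomes=1,
                    divergence_fst=0.0, ld_decay_bp=30_000, snp_spacing_bp=10_000)
    g, _ = simulate_two_populations(cfg)
    return g.subset_samples(g.samples_by_population("pop1"))


class TestPowerDistribution:
    def test_single_causal_with_duplicate_has_degenerate_quartiles(self):
        rng = np.random.default_rng(25)
        v = rng.binomial(2, 0.3, 300).astype(np.int8)
        calls = np.stack([v, v], axis=1)
        g = make_matrix(calls, positions=[1_000_000, 1_010_000])
        spec = PowerModelSpec(v_s=0.02, alpha_grid=(1e-5,))
        res = power_distribution(g, "1", spec)
        q = res[1e-5]
        expected = analytic_power(v.astype(float), v.astype(float), 0.02, 1e-5)
        assert q["q1"] == q["median"] == q["q3"] == pytest.approx(expected)

    def test_quartiles_monotone_in_effect_size(self, ld_chromosome):
        g = ld_chromosome
        res = {}
        for v_s in (0.02, 0.05):
            spec = PowerModelSpec(v_s=v_s, alpha_grid=(1e-5,))
            res[v_s] = power_distribution(g, "1", spec)[1e-5]
        for k in ("q1", "median", "q3"):
            assert res[0.05][k] >= res[0.02][k]

    def test_quartiles_monotone_in_sample_size(self, ld_chromosome):
        g = ld_chromosome
        spec = PowerModelSpec(v_s=0.02, alpha_grid=(1e-5,))
        full = power_distribution(g, "1", spec)[1e-5]
        sub = power_distribution(g.subset_samples(range(532)), "1", spec)[1e-5]
        for k in ("q1", "median", "q3"):
            assert full[k] > sub[k]
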