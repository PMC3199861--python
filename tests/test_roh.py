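import numpy as np
import pytest

from isopop.genotype_io import MISSING, GenotypeMatrix, SampleMeta, SnpMeta
from isopop.roh import (
    ROHParams,
    ROHRun,
    ROHSet,
    detect_roh,
    mean_total_roh_length,
    roh_length_class_summary,
)
from isopop.synthetic_data import SimConfig, simulate_two_populations


def _single(calls, positions, chrom="1"):
    snps = [SnpMeta(f"s{i}", chrom, int(p)) for i, p in enumerate(positions)]
    return GenotypeMatrix([SampleMeta("x")], snps,
                          np.asarray(calls, dtype=np.int8)[None, :])


def detect_roh_bruteforce(calls, pos, params: ROHParams):
    """Direct enumeration oracle: every window, every SNP vote, every segment."""
    m = len(pos)
    windows = []
    for i in range(m):
        j_end = i + params.window_min_snps
        if j_end > m:
            continue
        if pos[j_end - 1] - pos[i] > params.window_kb * 1000.0:
            continue
        w = calls[i:j_end]
        ok = (np.sum(w == 1) <= params.window_max_het
              and np.sum(w == MISSING) <= params.window_max_missing)
        windows.append((i, j_end, ok))
    flags = np.zeros(m, dtype=bool)
    for j in range(m):
        spanning = [ok for (i, e, ok) in windows if i <= j < e]
        if spanning:
            flags[j] = sum(spanning) / len(spanning) >= params.hit_proportion
    runs = []
    start = None
    segments = []
    for j in range(m):
        if flags[j]:
            if start is None:
                start = j
            elif pos[j] - pos[j - 1] >= params.gap_split_kb * 1000.0:
                segments.append((start, j - 1))
                start = j
        elif start is not None:
            segments.append((start, j - 1))
            start = None
    if start is not None:
        segments.append((start, m - 1))
    for s, e in segments:
        n_snps = e - s + 1
        length = pos[e] - pos[s]
        if (length >= params.min_run_kb * 1000.0
                and n_snps >= params.min_run_snps
                and length / 1000.0 / n_snps <= params.min_density_kb_per_snp):
            runs.append((int(pos[s]), int(pos[e]), n_snps))
    return runs


class TestDetect:
    def test_fully_homozygous_stretch_is_one_run(self):
        pos = np.linspace(100_000, 1_300_000, 150).astype(int)
        g = _single(np.zeros(150), pos)
        runs = detect_roh(g, "x").runs
        assert runs == [ROHRun("1", int(pos[0]), int(pos[-1]), 150)]

    def test_large_gap_splits_below_min_snps(self):
        pos = np.linspace(100_000, 1_300_000, 150).astype(int)
        pos[75:] += 150_000
        g = _single(np.zeros(150), pos)
        assert detect_roh(g, "x").runs == []

    def test_too_few_snps_is_no_run(self):
        pos = np.linspace(100_000, 700_000, 99).astype(int)
        g = _single(np.zeros(99), pos)
        assert detect_roh(g, "x").runs == []

    def test_unsorted_positions_rejected(self):
        g = _single([0, 0, 0], [300, 200, 100])
        with pytest.raises(ValueError, match="not sorted"):
            detect_roh(g, "x")

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(60, 500))
        pos = np.cumsum(rng.integers(1_000, 60_000, m))
        calls = rng.choice([0, 1, 2, MISSING], size=m,
                           p=[0.55, 0.15, 0.25, 0.05]).astype(np.int8)
        # seed in a homozygous stretch half of the time
        if seed % 2:
            a = int(rng.integers(0, m // 2))
            b = min(m, a + int(rng.integers(80, 250)))
            calls[a:b] = rng.choice([0, 2], size=b - a)
        params = ROHParams(window_min_snps=20, window_max_het=1,
                           window_max_missing=2, min_run_snps=40,
                           min_run_kb=300.0)
        g = _single(calls, pos)
        got = [(r.start_bp, r.end_bp, r.n_snps) for r in detect_roh(g, "x", params).runs]
        assert got == detect_roh_bruteforce(calls, pos, params)

    def test_no_cross_chromosome_leakage(self):
        pos = np.linspace(100_000, 1_300_000, 150).astype(int)
        g1 = _single(np.zeros(150), pos)
        snps2 = [SnpMeta(f"t{i}", "2", int(p)) for i, p in enumerate(pos)]
        g2 = GenotypeMatrix(
            [SampleMeta("x")],
            list(g1.snps) + snps2,
            np.hstack([g1.calls, np.ones((1, 150), dtype=np.int8)]),
        )
        assert detect_roh(g2, "x").runs == detect_roh(g1, "x").runs

    @pytest.mark.parametrize("seed", range(10))
    def test_relaxing_het_allowance_is_monotone(self, seed):
        rng = np.random.default_rng(1000 + seed)
        m = 300
        pos = np.cumsum(rng.integers(2_000, 20_000, m))
        calls = rng.choice([0, 1, 2], size=m, p=[0.45, 0.1, 0.45]).astype(np.int8)
        base = ROHParams(window_min_snps=20, min_run_snps=40, min_run_kb=300.0)
        relaxed = ROHParams(window_min_snps=20, min_run_snps=40, min_run_kb=300.0,
                            window_max_het=base.window_max_het + 1)
        g = _single(calls, pos)
        total = sum(r.length_bp for r in detect_roh(g, "x", base).runs)
        total_relaxed = sum(r.length_bp for r in detect_roh(g, "x", relaxed).runs)
        assert total_relaxed >= total


class TestSummaries:
    def test_no_runs_contribute_nowhere(self):
        sets = [ROHSet("a"), ROHSet("b")]
        assert roh_length_class_summary(sets, [(0, 1e6), (1e6, np.inf)]) == [0.0, 0.0]
        assert mean_total_roh_length(sets, [0, 1e6]) == [0.0, 0.0]

    def test_run_lands_in_single_bin(self):
        sets = [ROHSet("a", [ROHRun("1", 0, 3_000_000, 500)])]
        props = roh_length_class_summary(sets, [(2.5e6, 5e6), (5e6, np.inf)])
        assert props == [1.0, 0.0]

    def test_mean_total_length_grid(self):
        sets = [ROHSet("a", [ROHRun("1", 0, 600_000, 120),
                             ROHRun("1", 10_000_000, 12_000_000, 300)])]
        curve = mean_total_roh_length(sets, [0, 1e6])
        assert curve == [2_600_000.0, 2_000_000.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_total_length_curve_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for i in range(8):
            runs = [ROHRun("1", 0, int(rng.integers(5e5, 8e6)), 200)
                    for _ in range(rng.integers(0, 4))]
            sets.append(ROHSet(f"s{i}", runs))
        grid = [0, 5e5, 1e6, 2.5e6, 5e6]
        curve = mean_total_roh_length(sets, grid)
        assert all(a >= b for a, b in zip(curve, curve[1:]))

    def test_consanguineous_cohort_shows_intermediate_roh_excess(self):
        """Offspring of first-cousin matings carry 2.5-5 Mb autozygous runs
        that an outbred cohort of the same size lacks."""
        cfg = SimConfig(seed=12, n_pop1=220, n_pop2=2, n_snps=4000,
                        n_chromosomes=1, divergence_fst=0.0, ld_decay_bp=0,
                        snp_spacing_bp=10_000, recomb_rate_per_bp=5e-8,
                        family_spec=[("cousin-mating", 50)])
        g, _ = simulate_two_populations(cfg)
        inbred = [s for s in g.sample_ids if s.endswith("_inbred")][:50]
        outbred = [s for s in g.sample_ids if s.startswith("pop1_")][:50]
        sets_i = [detect_roh(g, s) for s in inbred]
        sets_o = [detect_roh(g, s) for s in outbred]
        bins = [(2.5e6, 5e6)]
        prop_i = roh_length_class_summary(sets_i, bins)[0]
        prop_o = roh_length_class_summary(sets_o, bins)[0]
        assert prop_i > prop_o
        assert prop_i >= 0.1
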