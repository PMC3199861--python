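"""Rare-SNP classification by exact binomial confidence interval.

A SNP is *rare* when the exact (Clopper-Pearson) 95% confidence interval
for its minor allele frequency lies entirely below 1%: equivalently, the
observed minor-allele count is at most the largest k whose upper exact
bound is still below the MAF cut.  At 1954 called chromosomes that is a
count below 11; at 1064 chromosomes a count below 5.  Cohorts are compared
with Fisher's exact test on the (rare / non-rare) x (cohort) table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "RareCriterion",
    "clopper_pearson_upper",
    "rare_count_threshold",
    "classify_rare",
    "compare_rare_odds",
]


@dataclass(frozen=True)
class RareCriterion:
    maf_bound: float = 0.01
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_bound < 0.5):
            raise ValueError("maf_bound must lie in (0, 0.5)")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must lie in (0, 1)")


def clopper_pearson_upper(k: int, n: int, confidence: float = 0.95) -> float:
    """Upper bound of the exact two-sided binomial interval for k of n."""
    if k >= n:
        return 1.0
    alpha = 1.0 - confidence
    return float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))


def rare_count_threshold(n_chromosomes: int, crit: RareCriterion = RareCriterion()) -> int | None:
    """Largest allele count still classified rare at ``n_chromosomes``, or None.

    Monotone in n: more chromosomes allow a larger absolute count below the
    same frequency bound.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least two chromosomes")
    if clopper_pearson_upper(0, n_chromosomes, crit.confidence) >= crit.maf_bound:
        return None
    k = 0
    while clopper_pearson_upper(k + 1, n_chromosomes, crit.confidence) < crit.maf_bound:
        k += 1
    return k


def classify_rare(
    g: GenotypeMatrix, crit: RareCriterion = RareCriterion()
) -> tuple[np.ndarray, int]:
    """Per-SNP rare flag and the cohort rare count.

    Rarity is judged at each SNP's *realized* called chromosome count, so
    missing genotypes tighten the criterion for that SNP.
    """
    calls = g.calls
    called = calls != MISSING
    n_chrom = 2 * called.sum(axis=0)
    b = np.where(called, calls, 0).sum(axis=0)
    minor = np.minimum(b, n_chrom - b)
    thresholds = np.full(g.n_snps, -1, dtype=np.int64)
    for n in np.unique(n_chrom):
        if n < 2:
            continue
        t = rare_count_threshold(int(n), crit)
        thresholds[n_chrom == n] = -1 if t is None else t
    flags = (minor <= thresholds) & (thresholds >= 0) & (n_chrom >= 2)
    return flags, int(flags.sum())


def compare_rare_odds(
    count_a: int, total_snps: int, count_b: int, total_snps_b: int | None = None
) -> tuple[float, float]:
    """Odds ratio and Fisher's exact two-sided p comparing rare-SNP yields.

    The two cohorts are assumed classified over the same SNP panel unless
    ``total_snps_b`` is given.
    """
    tb = total_snps if total_snps_b is None else total_snps_b
    if count_a > total_snps or count_b > tb:
        raise ValueError("counts cannot exceed totals")
    table = [[count_a, total_snps - count_a], [count_b, tb - count_b]]
    if count_a + count_b == 0 or (total_snps - count_a) + (tb - count_b) == 0:
        return 1.0, 1.0
    or_, p = stats.fisher_exact(table, alternative="two-sided")
    return float(or_), float(p)
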