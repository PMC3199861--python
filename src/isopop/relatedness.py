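"""Pairwise relatedness, unrelated-subset selection and pair summaries.

Relatedness between individuals i and j is the allele-frequency
standardized genomic estimator

    r_ij = mean over SNPs of (x_i - 2p)(x_j - 2p) / (2p(1-p)),

with p the in-sample frequency of the counted allele and the mean taken
over SNPs with MAF >= 0.01 where both individuals are called.  Its
expectation is 1 for self/duplicates, 0.5 for parent-offspring pairs, 0.25
for second-degree and 0 for unrelated pairs — the additive relationship
scale.

``select_unrelated`` implements the step-by-step removal heuristic: while
any pair exceeds the cutoff (strictly), drop the individual with the most
over-cutoff partners; ties go to the individual with the larger maximum
relatedness, then to the lexicographically larger id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .genotype_io import GenotypeMatrix

__all__ = [
    "RelatednessMatrix",
    "PairDistribution",
    "estimate_relatedness",
    "select_unrelated",
    "pair_distribution",
    "related_pair_odds_ratio",
    "n_pairs",
]


def n_pairs(n: int) -> int:
    """Number of unordered pairs among n individuals."""
    return n * (n - 1) // 2


@dataclass
class RelatednessMatrix:
    sample_ids: list[str]
    entries: np.ndarray  # symmetric, diagonal = self-relatedness

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        n = len(self.sample_ids)
        if self.entries.shape != (n, n):
            raise ValueError("relatedness matrix shape mismatch")
        if not np.allclose(self.entries, self.entries.T, equal_nan=True):
            raise ValueError("relatedness matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.entries[iu]

    def subset(self, ids: list[str]) -> "RelatednessMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return RelatednessMatrix(list(ids), self.entries[np.ix_(idx, idx)])


@dataclass
class PairDistribution:
    lower_bounds: list[float]
    counts: list[int]
    total_pairs: int

    def __post_init__(self) -> None:
        if any(c2 > c1 for c1, c2 in zip(self.counts, self.counts[1:])):
            # counts over increasing bounds can only shrink
            raise ValueError("pair counts must be non-increasing in the bound")


def estimate_relatedness(g: GenotypeMatrix, maf_min: float = 0.01) -> RelatednessMatrix:
    """Genomic relatedness from standardized dosages, complete pairs only."""
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    d = g.dosage()
    p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if keep.sum() == 0:
        raise ValueError("no polymorphic SNPs with MAF above threshold")
    d = d[:, keep]
    p = p[keep]
    z = (d - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    called = ~np.isnan(z)
    z0 = np.where(called, z, 0.0)
    num = z0 @ z0.T
    cnt = called.astype(np.float64) @ called.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / cnt
    return RelatednessMatrix(g.sample_ids, r)


def select_unrelated(R: RelatednessMatrix, cutoff: float = 0.2) -> list[str]:
    """Ids retained after greedy removal until no pair exceeds ``cutoff``."""
    n = R.n
    active = np.ones(n, dtype=bool)
    E = R.entries.copy()
    np.fill_diagonal(E, -np.inf)
    over = E > cutoff
    while True:
        deg = np.where(active, (over & active[None, :]).sum(axis=1), -1)
        if deg.max() <= 0:
            break
        cand = np.where(deg == deg.max())[0]
        if cand.size > 1:
            maxr = np.array([
                E[i, active & over[i]].max() if (active & over[i]).any() else -np.inf
                for i in cand
            ])
            cand = cand[maxr == maxr.max()]
            if cand.size > 1:
                ids = [R.sample_ids[i] for i in cand]
                cand = np.array([cand[int(np.argmin(ids))]])
        active[cand[0]] = False
    return [R.sample_ids[i] for i in range(n) if active[i]]


def pair_distribution(
    R: RelatednessMatrix, lower_bounds: list[float] = (0.1, 0.2, 0.4, 0.6)
) -> PairDistribution:
    """Counts of unordered pairs with relatedness strictly above each bound."""
    vals = R.pair_values()
    bounds = sorted(lower_bounds)
    counts = [int((vals > b).sum()) for b in bounds]
    return PairDistribution(bounds, counts, n_pairs(R.n))


def related_pair_odds_ratio(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    level: float = 0.95,
    method: str = "sample",
) -> tuple[float, tuple[float, float]]:
    """Odds ratio (cohort A vs reference cohort B) for carrying a related pair.

    ``method='sample'`` gives the sample odds ratio with a Woolf (log-normal)
    interval; ``method='cmle'`` the conditional maximum-likelihood odds
    ratio with its exact interval.  A zero reference count returns an
    unbounded estimate with a one-sided interval.
    """
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must satisfy 0 <= count <= total")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    if method == "cmle":
        res = _cond_odds_ratio(table)
        ci = res.confidence_interval(confidence_level=level)
        return float(res.statistic), (float(ci.low), float(ci.high))
    if method != "sample":
        raise ValueError("method must be 'sample' or 'cmle'")
    if count_b == 0:
        lo = _woolf_bound(count_a, total_a, 0.5, total_b, level, lower=True)
        return math.inf, (lo, math.inf)
    odds_a = count_a / (total_a - count_a)
    odds_b = count_b / (total_b - count_b)
    or_ = odds_a / odds_b
    if count_a == 0:
        hi = _woolf_bound(0.5, total_a, count_b, total_b, level, lower=False)
        return 0.0, (0.0, hi)
    se = math.sqrt(
        1.0 / count_a + 1.0 / (total_a - count_a) + 1.0 / count_b + 1.0 / (total_b - count_b)
    )
    z = norm.ppf(0.5 + level / 2.0)
    return or_, (or_ * math.exp(-z * se), or_ * math.exp(z * se))


def _woolf_bound(ca, ta, cb, tb, level, lower):
    or_ = (ca / (ta - ca)) / (cb / (tb - cb))
    se = math.sqrt(1.0 / ca + 1.0 / (ta - ca) + 1.0 / cb + 1.0 / (tb - cb))
    z = norm.ppf(level)  # one-sided
    return or_ * math.exp(-z * se) if lower else or_ * math.exp(z * se)
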