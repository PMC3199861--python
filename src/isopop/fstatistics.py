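"""Weir-Cockerham F-statistics with delete-one-individual jackknife errors.

Per-SNP variance components for two alleles (a: among populations, b: among
individuals within populations, c: within individuals) are combined over
SNPs as a ratio of sums ("weighted average"), never a mean of per-SNP
ratios:

    theta (F_ST) = sum(a) / sum(a + b + c)
    f     (F_IS) = 1 - sum(c) / sum(b + c)

Missing genotypes enter through per-SNP complete-case sample sizes.
Standard errors come from the delete-one-individual jackknife; the
leave-one-out estimates are recomputed from cached per-population allele
and heterozygote counts, so a full jackknife costs O(n_individuals x
n_snps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["FStatResult", "fis", "fst", "jackknife_se", "jackknife_se_generic"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FStatResult:
    statistic: str
    estimate: float
    se: float
    n_snps: int
    n_individuals: int


def _pop_sufficient_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (called count, allele-B count, het count) for one population."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(np.float64)
    b = np.where(called, calls, 0).sum(axis=0).astype(np.float64)
    h = (calls == 1).sum(axis=0).astype(np.float64)
    return n, b, h


def _theta_from_stats(stats_list: list[tuple[np.ndarray, np.ndarray, np.ndarray]]) -> float:
    """Weir-Cockerham theta from per-population sufficient statistics."""
    r = len(stats_list)
    n_i = np.stack([s[0] for s in stats_list])  # r x m
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = np.stack([s[1] for s in stats_list]) / (2.0 * n_i)
        h_i = np.stack([s[2] for s in stats_list]) / n_i
    valid = (n_i >= 2).all(axis=0)
    n_i, p_i, h_i = n_i[:, valid], p_i[:, valid], h_i[:, valid]

    n_bar = n_i.mean(axis=0)
    n_sum = r * n_bar
    nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / n_sum
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / n_sum

    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0
    a = n_bar / nc * (s2 - inner / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("no informative SNPs for theta")
    return float(a.sum() / denom)


def _fis_from_stats(n: np.ndarray, bcnt: np.ndarray, h: np.ndarray) -> float:
    valid = n >= 2
    n, bcnt, h = n[valid], bcnt[valid], h[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = bcnt / (2.0 * n)
        hf = h / n
    b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hf)
    c = hf / 2.0
    denom = (b + c).sum()
    if denom == 0:
        raise ValueError("no polymorphic SNPs for F_IS")
    return float(1.0 - c.sum() / denom)


def _jackknife_from_loo(loo: np.ndarray) -> float:
    loo = np.asarray(loo, dtype=np.float64)
    loo = loo[np.isfinite(loo)]
    n = loo.size
    if n < 3:
        raise ValueError("need at least three jackknife units")
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))


def fis(g: GenotypeMatrix, population: str | None = None, compute_se: bool = True) -> FStatResult:
    """Within-population inbreeding coefficient with jackknife SE."""
    if population is not None:
        g = g.subset_samples(g.samples_by_population(population))
    if g.n_samples < 2:
        raise ValueError("need at least two individuals")
    n, b, h = _pop_sufficient_stats(g.calls)
    est = _fis_from_stats(n, b, h)
    if not compute_se:
        return FStatResult("F_IS", est, float("nan"), g.n_snps, g.n_samples)

    loo = np.empty(g.n_samples)
    for i in range(g.n_samples):
        row = g.calls[i]
        called = row != MISSING
        n2 = n - called
        b2 = b - np.where(called, row, 0)
        h2 = h - (row == 1)
        try:
            loo[i] = _fis_from_stats(n2, b2, h2)
        except ValueError:
            loo[i] = np.nan
            logger.warning("F_IS undefined with individual %s removed; skipped", g.samples[i].sample_id)
    se = _jackknife_from_loo(loo)
    return FStatResult("F_IS", est, se, g.n_snps, g.n_samples)


def fst(g: GenotypeMatrix, pop_a: str, pop_b: str, compute_se: bool = True) -> FStatResult:
    """Pairwise Weir-Cockerham theta with jackknife-over-individuals SE.

    Each deleted individual is removed from its own population only.
    """
    idx_a = g.samples_by_population(pop_a)
    idx_b = g.samples_by_population(pop_b)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each population needs at least two individuals")
    calls_a, calls_b = g.calls[idx_a], g.calls[idx_b]
    stats_a = _pop_sufficient_stats(calls_a)
    stats_b = _pop_sufficient_stats(calls_b)
    est = _theta_from_stats([stats_a, stats_b])
    if not compute_se:
        return FStatResult("F_ST", est, float("nan"), g.n_snps, int(idx_a.size + idx_b.size))

    loo = []
    for calls, stats, other in ((calls_a, stats_a, stats_b), (calls_b, stats_b, stats_a)):
        n, b, h = stats
        for i in range(calls.shape[0]):
            row = calls[i]
            called = row != MISSING
            reduced = (n - called, b - np.where(called, row, 0), h - (row == 1))
            try:
                loo.append(_theta_from_stats([reduced, other]))
            except ValueError:
                loo.append(np.nan)
    se = _jackknife_from_loo(np.array(loo))
    return FStatResult("F_ST", est, se, g.n_snps, int(idx_a.size + idx_b.size))


def jackknife_se_generic(
    statistic: Callable[[GenotypeMatrix], float], g: GenotypeMatrix
) -> float:
    """Delete-one-individual jackknife SE of an arbitrary functional of g.

    sqrt((n-1)/n * sum((theta_(i) - theta_bar)^2)); leave-one-out subsets on
    which the statistic is undefined are skipped with a warning.
    """
    n = g.n_samples
    if n < 3:
        raise ValueError("need at least three individuals")
    loo = np.empty(n)
    for i in range(n):
        sub = g.subset_samples([j for j in range(n) if j != i])
        try:
            loo[i] = statistic(sub)
        except Exception:
            loo[i] = np.nan
            logger.warning("statistic undefined without individual %s; skipped", g.samples[i].sample_id)
    return _jackknife_from_loo(loo)


# spec surface name
jackknife_se = jackknife_se_generic
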