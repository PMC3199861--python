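"""SNP quality control: call rate, stratified HWE, platform frequency test.

Three per-SNP filters are applied and their union removed:

1. combined-cohort call rate below a threshold (default 0.95, strict);
2. a stratified Hardy-Weinberg test that sums signed heterozygote deficits
   across population strata (robust to the Wahlund effect that a naive
   pooled test mistakes for HWE violation), default threshold p < 1e-6;
3. a platform allele-frequency test comparing the two genotyping platforms
   within one population (exact test for sparse tables), default p < 1e-7.

The stratified HWE statistic uses the exact conditional moments of the
heterozygote count given the stratum allele count (random pairing of 2n
alleles into n genotypes), so it is finite-sample corrected:
``E[h | a] = a(2n-a)/(2n-1)`` and the matching exact variance.  Deficits
``d_s = O_het,s - E_het,s`` are summed over strata and referred to a normal
with a continuity correction of one (the het count steps by 2 given the
allele count): ``Z = max(|sum(d_s)| - 1, 0) / sqrt(sum(Var_s))``.  In a
single stratum this is the one-population score-type HWE test on the exact
conditional moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "call_rate_filter",
    "hwe_exact_moments",
    "stratified_hwe_test",
    "platform_frequency_test",
    "apply_qc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.95
    hwe_p: float = 1e-6
    platform_p: float = 1e-7
    pca_call_rate: float = 0.99

    def __post_init__(self) -> None:
        for v in (self.min_call_rate, self.hwe_p, self.platform_p, self.pca_call_rate):
            if not (0.0 <= v <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: set[str] = field(default_factory=set)
    removed_hwe: set[str] = field(default_factory=set)
    removed_platform: set[str] = field(default_factory=set)

    @property
    def removed_union(self) -> set[str]:
        return self.removed_call_rate | self.removed_hwe | self.removed_platform

    @property
    def n_removed_union(self) -> int:
        return len(self.removed_union)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_union

    def summary(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "removed_call_rate": len(self.removed_call_rate),
            "removed_hwe": len(self.removed_hwe),
            "removed_platform": len(self.removed_platform),
            "n_removed_union": self.n_removed_union,
            "n_retained": self.n_retained,
        }


def call_rate_filter(g: GenotypeMatrix, thresholds: QCThresholds | None = None) -> set[str]:
    """SNP ids whose combined (all-sample) call rate is strictly below the cut."""
    thresholds = thresholds or QCThresholds()
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    rates = g.call_rate()
    fail = rates < thresholds.min_call_rate
    return {g.snps[j].snp_id for j in np.where(fail)[0]}


def hwe_exact_moments(n_called: np.ndarray, b_count: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and variance of the heterozygote count under HWE.

    Conditional on ``b_count`` copies of allele B among ``2 * n_called``
    alleles, random pairing into genotypes gives
    ``E[h] = a(2n-a)/(2n-1)`` and
    ``E[h(h-1)] = a(a-1)(2n-a)(2n-a-1)/((2n-1)(2n-3))``.
    Vectorized over SNPs; degenerate strata (n < 2) return zero variance.
    """
    n = np.asarray(n_called, dtype=np.float64)
    a = np.asarray(b_count, dtype=np.float64)
    two_n = 2.0 * n
    with np.errstate(divide="ignore", invalid="ignore"):
        e_h = a * (two_n - a) / (two_n - 1.0)
        e_h2 = a * (a - 1.0) * (two_n - a) * (two_n - a - 1.0) / (
            (two_n - 1.0) * (two_n - 3.0)
        ) + e_h
        var_h = e_h2 - e_h**2
    bad = n < 2
    e_h = np.where(bad, 0.0, e_h)
    var_h = np.where(bad, 0.0, np.maximum(var_h, 0.0))
    return e_h, var_h


def stratified_hwe_test(g: GenotypeMatrix, strata: np.ndarray | list[str] | None = None) -> np.ndarray:
    """Per-SNP two-sided p-value of the stratified HWE test.

    ``strata`` defaults to sample population labels.  SNPs monomorphic in
    every stratum carry no information and get p = 1.
    """
    if strata is None:
        strata = [s.population for s in g.samples]
    strata = np.asarray(strata)
    calls = g.calls
    num = np.zeros(g.n_snps)
    den = np.zeros(g.n_snps)
    for label in np.unique(strata):
        rows = strata == label
        sub = calls[rows, :]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        b_count = np.where(called, sub, 0).sum(axis=0)
        o_het = (sub == 1).sum(axis=0)
        e_het, var_het = hwe_exact_moments(n_called, b_count)
        num += o_het - e_het
        den += var_het
    # the het count moves in steps of 2 given the allele count, so a
    # continuity correction of 1 keeps the far normal tail honest
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(num) - 1.0, 0.0) / np.sqrt(den)
    p = np.where(den > 0, 2.0 * stats.norm.sf(z), 1.0)
    return p


def platform_frequency_test(
    g: GenotypeMatrix,
    platforms: np.ndarray | list[str] | None = None,
    within: str | None = None,
) -> np.ndarray:
    """Per-SNP two-sided p for allele-frequency differences between platforms.

    Builds the 2x2 allele-count table between the two platform strata
    (optionally restricted to one population) and tests it with a
    chi-square, falling back to Fisher's exact test when any expected cell
    count is below 5.  SNPs typed on fewer than two platforms get NaN.
    """
    idx = np.arange(g.n_samples)
    if within is not None:
        idx = g.samples_by_population(within)
    if platforms is None:
        platforms = np.array([g.samples[i].platform or "" for i in idx])
    else:
        platforms = np.asarray(platforms)[idx]
    labels = [l for l in np.unique(platforms) if l]
    if len(labels) != 2:
        raise ValueError(f"need exactly two platform labels, got {labels}")
    calls = g.calls[idx, :]
    p_out = np.full(g.n_snps, np.nan)
    tables = []
    for label in labels:
        sub = calls[platforms == label, :]
        called = sub != MISSING
        n_alleles = 2 * called.sum(axis=0)
        b = np.where(called, sub, 0).sum(axis=0)
        tables.append((b, n_alleles - b, n_alleles))
    (b1, a1, n1), (b2, a2, n2) = tables
    total = n1 + n2
    informative = (n1 > 0) & (n2 > 0)
    # chi-square without continuity correction on well-filled tables
    with np.errstate(divide="ignore", invalid="ignore"):
        row_b = b1 + b2
        row_a = a1 + a2
        exp = np.stack([
            n1 * row_b / total, n1 * row_a / total,
            n2 * row_b / total, n2 * row_a / total,
        ])
        obs = np.stack([b1, a1, b2, a2]).astype(np.float64)
        chi2 = np.nansum((obs - exp) ** 2 / exp, axis=0)
    monomorphic = (row_b == 0) | (row_a == 0)
    p_chi = stats.chi2.sf(chi2, df=1)
    small = informative & ~monomorphic & (exp.min(axis=0) < 5)
    p_out[informative] = p_chi[informative]
    p_out[informative & monomorphic] = 1.0
    for j in np.where(small)[0]:
        _, p_out[j] = stats.fisher_exact(
            [[b1[j], a1[j]], [b2[j], a2[j]]], alternative="two-sided"
        )
    skipped = np.where(~informative)[0]
    if skipped.size:
        logger.info("platform test skipped for %d SNP(s) typed on one platform", skipped.size)
    return p_out


def apply_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    platform_within: str | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove the union of call-rate, HWE and platform failures."""
    thresholds = thresholds or QCThresholds()
    report = QCReport(n_input=g.n_snps)
    report.removed_call_rate = call_rate_filter(g, thresholds)

    p_hwe = stratified_hwe_test(g)
    report.removed_hwe = {
        g.snps[j].snp_id for j in np.where(p_hwe < thresholds.hwe_p)[0]
    }

    has_platforms = len({s.platform for s in g.samples if s.platform}) == 2
    if has_platforms:
        p_plat = platform_frequency_test(g, within=platform_within)
        with np.errstate(invalid="ignore"):
            fail = p_plat < thresholds.platform_p
        report.removed_platform = {g.snps[j].snp_id for j in np.where(fail)[0]}

    removed = report.removed_union
    keep = [j for j in range(g.n_snps) if g.snps[j].snp_id not in removed]
    if not keep:
        raise ValueError("quality control removed every SNP")
    return g.subset_snps(keep), report
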