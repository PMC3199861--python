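"""Synthetic two-cohort genotype generator with recorded ground truth.

The generator emulates the statistical structure a comparison of an isolate
cohort against an outbred cohort rests on:

* two populations diverged by a small F_ST, via the Balding–Nichols
  model (population allele frequencies Beta-distributed around a shared
  ancestral frequency with variance parameter F);
* linkage disequilibrium decaying with physical distance, via a Gaussian
  copula AR(1) haplotype process whose latent autocorrelation between
  adjacent SNPs is exp(-d / ld_decay_bp) — marginal allele frequencies are
  exact, pairwise haplotype association decays smoothly with distance;
* oversampled families (parent-offspring trios, sib pairs, cousin pairs,
  consanguineous cousin matings) built by Mendelian transmission of founder
  haplotypes with recombination;
* per-platform missingness and platform-specific allele-frequency shifts,
  the artifacts a platform frequency test is meant to catch.

Every run records its ground truth (ancestral and population frequencies,
pedigree, expected additive relationship matrix, artifact SNP ids) so that
estimator-recovery tests can compare against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .genotype_io import MISSING, GenotypeMatrix, SampleMeta, SnpMeta

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_two_populations",
    "overlay_families",
    "inject_artifacts",
]

FAMILY_TYPES = ("parent-offspring", "sib-pair", "cousin-pair", "cousin-mating")


@dataclass
class SimConfig:
    """Parameters of a synthetic two-cohort study.

    Defaults describe the study conditions emulated throughout: two cohorts
    diverged at F_ST ~ 0.003, common SNPs, LD on a tens-of-kb scale and a
    platform split within the first cohort.
    """

    seed: int = 0
    n_pop1: int = 300
    n_pop2: int = 300
    n_snps: int = 20_000
    n_chromosomes: int = 2
    divergence_fst: float = 0.003
    pop_fst: tuple[float, float] | None = None  # per-population drift; default symmetric
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_bp: float = 50_000.0  # 0 disables LD (independent SNPs)
    snp_spacing_bp: float = 10_000.0  # mean inter-SNP distance
    family_spec: list[tuple[str, int]] = field(default_factory=list)
    missing_rate_by_platform: dict[str, float] = field(default_factory=dict)
    platform_shift_snps: tuple[int, float] = (0, 0.0)
    inbred_fraction: float = 0.0  # fraction of pop1 matings between first cousins
    # The toy genome is physically compressed (~10 kb SNP spacing, tens of Mb
    # per chromosome); 1e-7 /bp keeps the *genetic* map at a realistic tens of
    # Morgans so realized relatedness varies around pedigree expectations as
    # it does genome-wide, not an order of magnitude more.
    recomb_rate_per_bp: float = 1e-7
    pop_labels: tuple[str, str] = ("pop1", "pop2")
    platform_labels: tuple[str, str] = ("chipA", "chipB")

    def validate(self) -> None:
        if not (0.0 <= self.divergence_fst < 0.5):
            raise ValueError("divergence_fst must lie in [0, 0.5)")
        if self.pop_fst is not None and not all(0.0 <= f < 0.5 for f in self.pop_fst):
            raise ValueError("pop_fst entries must lie in [0, 0.5)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.ld_decay_bp < 0:
            raise ValueError("ld_decay_bp must be >= 0")
        for prop in (self.inbred_fraction, *self.missing_rate_by_platform.values()):
            if not (0.0 <= prop <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")
        for ftype, count in self.family_spec:
            if ftype not in FAMILY_TYPES:
                raise ValueError(f"unknown family type {ftype!r}")
            if count < 0:
                raise ValueError("family counts must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort pair.

    ``true_kinship`` is on the relatedness scale where a non-inbred
    individual has diagonal 1 and a parent-offspring pair expectation 0.5
    (the numerator relationship matrix A).
    """

    ancestral_freqs: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    true_kinship: np.ndarray | None = None
    artifact_snps: list[str] = field(default_factory=list)
    haplotypes: np.ndarray | None = None  # (2*n_samples, n_snps) int8, phased


def _derive_rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


def _snp_map(cfg: SimConfig, rng: np.random.Generator) -> list[SnpMeta]:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    snps: list[SnpMeta] = []
    k = 0
    for c in range(cfg.n_chromosomes):
        gaps = rng.exponential(cfg.snp_spacing_bp, size=per_chrom[c])
        pos = np.maximum(1, np.cumsum(np.maximum(gaps, 1.0)).astype(np.int64))
        pos = np.unique(pos)
        while pos.size < per_chrom[c]:  # rare collisions after rounding
            extra = pos[-1] + np.cumsum(
                np.maximum(rng.exponential(cfg.snp_spacing_bp, per_chrom[c] - pos.size), 1.0)
            ).astype(np.int64)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[: per_chrom[c]]
        for p in pos:
            snps.append(SnpMeta(f"snp{k}", str(c + 1), int(p), "A", "G"))
            k += 1
    return snps


def _haplotype_pool(
    freqs: np.ndarray,
    snps: Sequence[SnpMeta],
    n_hap: int,
    ld_decay_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n_hap haplotypes with AR(1) latent correlation along each chromosome."""
    m = freqs.size
    if ld_decay_bp <= 0:
        return (rng.random((n_hap, m)) < freqs[None, :]).astype(np.int8)
    z = np.empty((n_hap, m))
    chroms = np.array([s.chromosome for s in snps])
    pos = np.array([s.position_bp for s in snps], dtype=np.float64)
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    rho = np.exp(-np.diff(pos, prepend=pos[0]) / ld_decay_bp)
    rho[new_chrom] = 0.0
    eps = rng.standard_normal((n_hap, m))
    z[:, 0] = eps[:, 0]
    for j in range(1, m):
        r = rho[j]
        z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j]
    thresh = norm.ppf(freqs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_two_populations(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate two diverged cohorts; families from ``cfg.family_spec`` are
    overlaid on the first population, inbred matings per ``cfg.inbred_fraction``."""
    cfg.validate()
    rng = _derive_rng(cfg.seed, 1)
    snps = _snp_map(cfg, rng)
    m = len(snps)
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    # Balding-Nichols drift; each population may drift by its own F so an
    # isolate can sit further from the shared ancestor than the outbred cohort
    fs = cfg.pop_fst or (cfg.divergence_fst, cfg.divergence_fst)
    pop_freqs = {}
    for label, f in zip(cfg.pop_labels, fs):
        if f == 0:
            pop_freqs[label] = p_anc.copy()
        else:
            shape = (1.0 - f) / f
            pop_freqs[label] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)

    n_total = cfg.n_pop1 + cfg.n_pop2
    haplos = np.empty((2 * n_total, m), dtype=np.int8)
    samples: list[SampleMeta] = []
    offset = 0
    for label, n_pop in zip(cfg.pop_labels, (cfg.n_pop1, cfg.n_pop2)):
        pool = _haplotype_pool(pop_freqs[label], snps, 2 * n_pop, cfg.ld_decay_bp, rng)
        haplos[2 * offset : 2 * (offset + n_pop)] = pool
        for i in range(n_pop):
            platform = None
            if label == cfg.pop_labels[0] and cfg.missing_rate_by_platform:
                platform = cfg.platform_labels[i % 2]
            samples.append(SampleMeta(f"{label}_{i}", population=label, platform=platform))
        offset += n_pop

    calls = (haplos[0::2] + haplos[1::2]).astype(np.int8)
    g = GenotypeMatrix(samples, snps, calls)
    truth = TruthRecord(
        ancestral_freqs=p_anc,
        pop_freqs=pop_freqs,
        true_kinship=np.eye(n_total),
        haplotypes=haplos,
    )
    if cfg.family_spec or cfg.inbred_fraction > 0:
        g, truth = overlay_families(g, truth, cfg.family_spec, cfg=cfg)
    return g, truth


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------


def _meiosis(
    hap_pair: np.ndarray,
    snps: Sequence[SnpMeta],
    rate_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a phased parent: recombine with exponential
    inter-crossover distances, independent chromosomes."""
    m = hap_pair.shape[1]
    source = np.empty(m, dtype=np.int8)
    chroms = np.array([s.chromosome for s in snps])
    pos = np.array([s.position_bp for s in snps], dtype=np.float64)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        cpos = pos[idx]
        length = cpos[-1] - cpos[0]
        cur = rng.integers(0, 2)
        if rate_per_bp > 0:
            n_x = rng.poisson(length * rate_per_bp)
            xs = np.sort(rng.uniform(cpos[0], cpos[-1], size=n_x))
            flips = np.searchsorted(xs, cpos, side="left") % 2
            source[idx] = (cur + flips) % 2
        else:
            source[idx] = cur
    return hap_pair[source, np.arange(m)]


def _expected_relationship(
    pedigree: dict[str, tuple[str, str]], order: list[str], base: dict[str, int] | None,
    base_matrix: np.ndarray | None,
) -> np.ndarray:
    """Numerator relationship matrix by the tabular method; founders are the
    rows/cols of ``base_matrix`` (identity for unrelated founders)."""
    n = len(order)
    idx = {s: i for i, s in enumerate(order)}
    A = np.zeros((n, n))
    if base is not None and base_matrix is not None:
        for s1, i1 in base.items():
            for s2, i2 in base.items():
                A[idx[s1], idx[s2]] = base_matrix[i1, i2]
    # order lists parents before offspring, so a single forward pass suffices
    for s in order:
        if s not in pedigree:
            continue
        i = idx[s]
        fa, mo = pedigree[s]
        fi, mi = idx[fa], idx[mo]
        for t in order:
            j = idx[t]
            if j == i:
                break
            A[i, j] = A[j, i] = 0.5 * (A[j, fi] + A[j, mi])
        A[i, i] = 1.0 + 0.5 * A[fi, mi]
    return A


def overlay_families(
    g: GenotypeMatrix,
    truth: TruthRecord,
    family_spec: Sequence[tuple[str, int]],
    cfg: SimConfig | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Append family members to the first population by Mendelian transmission.

    Founders are drawn (without replacement) from the first population;
    offspring are appended as new samples.  ``truth.pedigree`` and
    ``truth.true_kinship`` are updated from the pedigree.
    """
    if truth.haplotypes is None:
        raise ValueError("overlay_families requires phased truth haplotypes")
    cfg = cfg or SimConfig()
    rng = _derive_rng(cfg.seed, 2)
    rate = cfg.recomb_rate_per_bp
    snps = g.snps
    pop1 = cfg.pop_labels[0]

    founder_pool = [s.sample_id for s in g.samples if s.population == pop1]
    rng.shuffle(founder_pool)
    hap_of: dict[str, np.ndarray] = {
        s.sample_id: truth.haplotypes[2 * i : 2 * i + 2]
        for i, s in enumerate(g.samples)
    }
    pedigree: dict[str, tuple[str, str]] = dict(truth.pedigree)
    new_samples: list[SampleMeta] = []

    def take_founder(tag: str) -> str:
        if not founder_pool:
            raise ValueError(f"not enough founders in {pop1} for requested {tag}")
        return founder_pool.pop()

    def make_child(cid: str, fa: str, mo: str) -> None:
        child = np.stack(
            [_meiosis(hap_of[fa], snps, rate, rng), _meiosis(hap_of[mo], snps, rate, rng)]
        )
        hap_of[cid] = child
        pedigree[cid] = (fa, mo)
        meta = next(
            (s for s in list(g.samples) + new_samples if s.sample_id == fa), None
        )
        platform = meta.platform if meta is not None else None
        new_samples.append(SampleMeta(cid, population=pop1, platform=platform))

    spec = list(family_spec)
    if cfg.inbred_fraction > 0:
        n_cm = int(round(cfg.inbred_fraction * cfg.n_pop1 / 2))
        spec.append(("cousin-mating", n_cm))

    k = 0
    for ftype, count in spec:
        for _ in range(count):
            k += 1
            if ftype == "parent-offspring":
                fa, mo = take_founder(ftype), take_founder(ftype)
                make_child(f"fam{k}_child", fa, mo)
            elif ftype == "sib-pair":
                fa, mo = take_founder(ftype), take_founder(ftype)
                make_child(f"fam{k}_sib1", fa, mo)
                make_child(f"fam{k}_sib2", fa, mo)
            elif ftype in ("cousin-pair", "cousin-mating"):
                # shared grandparent couple; two of their children marry in
                gfa, gmo = take_founder(ftype), take_founder(ftype)
                sp1, sp2 = take_founder(ftype), take_founder(ftype)
                make_child(f"fam{k}_p1", gfa, gmo)
                make_child(f"fam{k}_p2", gfa, gmo)
                make_child(f"fam{k}_c1", f"fam{k}_p1", sp1)
                make_child(f"fam{k}_c2", f"fam{k}_p2", sp2)
                if ftype == "cousin-mating":
                    make_child(f"fam{k}_inbred", f"fam{k}_c1", f"fam{k}_c2")
            else:  # pragma: no cover - validated upstream
                raise ValueError(f"unknown family type {ftype!r}")

    if not new_samples:
        return g, truth

    order = [s.sample_id for s in g.samples] + [s.sample_id for s in new_samples]
    new_hap = np.vstack([hap_of[sid] for sid in order])
    calls = (new_hap[0::2] + new_hap[1::2]).astype(np.int8)
    all_samples = list(g.samples) + new_samples

    base_idx = {s.sample_id: i for i, s in enumerate(g.samples)}
    A = _expected_relationship(pedigree, order, base_idx, truth.true_kinship)
    g2 = GenotypeMatrix(all_samples, list(snps), calls)
    truth2 = TruthRecord(
        ancestral_freqs=truth.ancestral_freqs,
        pop_freqs=truth.pop_freqs,
        pedigree=pedigree,
        true_kinship=A,
        artifact_snps=list(truth.artifact_snps),
        haplotypes=new_hap,
    )
    return g2, truth2


# ---------------------------------------------------------------------------
# Platform artifacts
# ---------------------------------------------------------------------------


def inject_artifacts(g: GenotypeMatrix, cfg: SimConfig) -> tuple[GenotypeMatrix, list[str]]:
    """Add per-platform missingness and platform allele-frequency shifts.

    Returns the modified matrix and the ids of frequency-shifted SNPs.
    The shift re-draws genotypes of the *second* platform's samples at the
    selected SNPs from HWE at a frequency moved by the configured effect.
    """
    cfg.validate()
    rng = _derive_rng(cfg.seed, 3)
    calls = g.calls.copy()
    platforms = np.array([s.platform or "" for s in g.samples])

    n_shift, effect = cfg.platform_shift_snps
    artifact_ids: list[str] = []
    if n_shift > 0:
        if not (platforms == cfg.platform_labels[1]).any():
            raise ValueError("platform labels not assigned; cannot inject shifts")
        rows = np.where(platforms == cfg.platform_labels[1])[0]
        snp_idx = rng.choice(g.n_snps, size=n_shift, replace=False)
        freqs = g.allele_freq()
        for j in snp_idx:
            p = freqs[j]
            target = p + effect if p + effect <= 1.0 else p - effect
            if not (0.0 <= target <= 1.0):
                warnings.warn(f"shift for {g.snps[j].snp_id} clipped to [0,1]")
                target = float(np.clip(target, 0.0, 1.0))
            calls[rows, j] = rng.binomial(2, target, size=rows.size).astype(np.int8)
            artifact_ids.append(g.snps[j].snp_id)

    for label, rate in cfg.missing_rate_by_platform.items():
        if rate <= 0:
            continue
        rows = np.where(platforms == label)[0]
        if rows.size == 0:
            continue
        mask = rng.random((rows.size, g.n_snps)) < rate
        sub = calls[rows, :]
        sub[mask] = MISSING
        calls[rows, :] = sub

    g2 = GenotypeMatrix(list(g.samples), list(g.snps), calls)
    return g2, artifact_ids
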