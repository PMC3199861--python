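"""Balanced-subsample PCA with outlier removal and local LD correction.

Population structure is summarized by principal components of the
individual x individual covariance of standardized genotypes.  To keep
unequal cohort sizes from distorting the axes, equally sized subsamples of
the *most unrelated* individuals per group are analysed.  Each SNP column
is standardized as (x - 2p) / sqrt(p(1-p)) (missing -> 0 after centering)
and residualized on the preceding ``ld_regress_snps`` SNPs of the same
chromosome, which strips local LD so that a handful of tight haplotype
blocks cannot masquerade as structure.  Individuals scoring beyond
``outlier_sigma`` standard deviations on any leading component are removed
and the decomposition repeated, up to ``n_outlier_iterations`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix
from .relatedness import RelatednessMatrix

__all__ = ["PCAConfig", "PCAResult", "balanced_subsample", "pca_with_outlier_removal"]


@dataclass(frozen=True)
class PCAConfig:
    n_per_group: int = 50
    n_outlier_iterations: int = 5
    ld_regress_snps: int = 2
    n_components: int = 10
    outlier_sigma: float = 6.0
    pca_call_rate: float = 0.99
    relatedness_cutoff: float = 0.2


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # retained individuals x components
    eigenvalues: np.ndarray
    removed_outliers: list[list[str]] = field(default_factory=list)


def balanced_subsample(
    g: GenotypeMatrix,
    groups: dict[str, list[str]],
    R: RelatednessMatrix,
    cfg: PCAConfig = PCAConfig(),
) -> list[str]:
    """Pick ``n_per_group`` of the most mutually unrelated ids per group.

    Greedy: grow each group's selection by the candidate with the fewest
    over-cutoff relationships to the already-selected ids, breaking ties on
    the smaller maximum relatedness, then on id.
    """
    pos = {s: i for i, s in enumerate(R.sample_ids)}
    chosen: list[str] = []
    for gname, members in groups.items():
        if len(members) < cfg.n_per_group:
            raise ValueError(
                f"group {gname!r} has {len(members)} members, needs {cfg.n_per_group}"
            )
        selected: list[str] = []
        pool = sorted(members)
        while len(selected) < cfg.n_per_group:
            best = None
            for cand in pool:
                rels = [R.entries[pos[cand], pos[s]] for s in selected]
                n_over = sum(1 for r in rels if r > cfg.relatedness_cutoff)
                max_r = max(rels, default=-np.inf)
                key = (n_over, max_r, cand)
                if best is None or key < best[0]:
                    best = (key, cand)
            selected.append(best[1])
            pool.remove(best[1])
        chosen.extend(selected)
    return chosen


def _standardize_and_residualize(
    g: GenotypeMatrix, keep_rows: np.ndarray, ld_regress_snps: int
) -> np.ndarray:
    d = g.dosage()[keep_rows, :]
    p = np.nanmean(d, axis=0) / 2.0
    sd = np.sqrt(p * (1.0 - p))
    poly = (sd > 0) & ~np.isnan(sd)
    d = d[:, poly]
    p = p[poly]
    sd = sd[poly]
    x = (d - 2.0 * p[None, :]) / sd[None, :]
    x = np.nan_to_num(x, nan=0.0)
    if ld_regress_snps > 0:
        chroms = g.chromosomes[poly]
        resid = x.copy()
        for j in range(x.shape[1]):
            lo = max(0, j - ld_regress_snps)
            pred_idx = [k for k in range(lo, j) if chroms[k] == chroms[j]]
            if not pred_idx:
                continue
            Z = x[:, pred_idx]
            beta, *_ = np.linalg.lstsq(Z, x[:, j], rcond=None)
            resid[:, j] = x[:, j] - Z @ beta
        x = resid
    return x


def pca_with_outlier_removal(g: GenotypeMatrix, cfg: PCAConfig = PCAConfig()) -> PCAResult:
    """PCA of standardized, LD-corrected genotypes with iterative outlier removal."""
    snp_keep = np.where(g.call_rate() >= cfg.pca_call_rate)[0]
    if snp_keep.size == 0:
        raise ValueError("no SNPs pass the PCA call-rate threshold")
    g = g.subset_snps(snp_keep)
    retained = np.arange(g.n_samples)
    removed_log: list[list[str]] = []
    scores = eigenvalues = None
    for _ in range(cfg.n_outlier_iterations + 1):
        if retained.size < 10:
            raise ValueError("fewer than 10 individuals left after outlier removal")
        x = _standardize_and_residualize(g, retained, cfg.ld_regress_snps)
        cov = (x @ x.T) / x.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = min(cfg.n_components, evecs.shape[1])
        scores = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))[None, :]
        # orient each axis so its largest-magnitude loading is positive
        loadings = x.T @ evecs[:, :k]
        for c in range(k):
            top = np.argmax(np.abs(loadings[:, c]))
            if loadings[top, c] < 0:
                scores[:, c] *= -1.0
        eigenvalues = evals[:k]
        sds = scores.std(axis=0, ddof=1)
        sds[sds == 0] = np.inf
        out_mask = (np.abs(scores) > cfg.outlier_sigma * sds[None, :]).any(axis=1)
        if not out_mask.any() or len(removed_log) >= cfg.n_outlier_iterations:
            break
        removed_log.append([g.samples[retained[i]].sample_id for i in np.where(out_mask)[0]])
        retained = retained[~out_mask]
    return PCAResult(
        [g.samples[i].sample_id for i in retained],
        scores,
        eigenvalues,
        removed_log,
    )
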