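"""Runs of homozygosity by sliding-window voting.

The caller mirrors the classic windowed procedure: a window anchored at
each SNP covers the next ``window_min_snps`` SNPs (capped at a bp span of
``window_kb``; windows running past the chromosome end or the span cap are
not scored) and is judged homozygous when it contains at most
``window_max_het`` heterozygotes and ``window_max_missing`` missing calls;
each SNP is voted "in" when at least ``hit_proportion`` of the scored
windows spanning it are homozygous; maximal stretches of "in" SNPs are
split at inter-SNP gaps of ``gap_split_kb`` or more and reported when they
are long enough (``min_run_kb``), SNP-dense enough (one SNP per
``min_density_kb_per_snp``) and contain at least ``min_run_snps`` SNPs.

The window is counted in SNPs, not bp: a fixed bp-span window as long as
``window_kb`` could never be homozygous inside a run shorter than the span,
which would make every run below 5 Mb invisible — incompatible with a
500-kb minimum run length.  ``window_kb`` therefore acts as a span cap for
sparse regions, exactly the role it plays in the tool this parameterization
comes from.

Run length is the bp span from first to last SNP of the run.  A
heterozygote inside a reported run is possible — window voting, not
post-filtering, decides membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["ROHParams", "ROHRun", "ROHSet", "detect_roh", "detect_roh_cohort",
           "roh_length_class_summary", "mean_total_roh_length"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    window_kb: float = 5000.0
    window_min_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_proportion: float = 0.05
    min_run_kb: float = 500.0
    min_run_snps: int = 100
    min_density_kb_per_snp: float = 50.0
    gap_split_kb: float = 100.0

    def __post_init__(self) -> None:
        if self.min_run_kb > self.window_kb:
            raise ValueError("min_run_kb cannot exceed window_kb")
        for v in (self.window_kb, self.window_min_snps, self.hit_proportion,
                  self.min_run_kb, self.min_run_snps, self.min_density_kb_per_snp,
                  self.gap_split_kb):
            if v <= 0:
                raise ValueError("ROH parameters must be positive")


@dataclass(frozen=True)
class ROHRun:
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class ROHSet:
    sample_id: str
    runs: list[ROHRun] = field(default_factory=list)

    def total_length_bp(self, min_length_bp: float = 0.0) -> float:
        return float(sum(r.length_bp for r in self.runs if r.length_bp >= min_length_bp))


def _in_segment_flags(calls: np.ndarray, pos: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean "in a homozygous segment" flag per SNP of one chromosome."""
    m = pos.size
    window_bp = params.window_kb * 1000.0
    # window i covers the next window_min_snps SNPs: [i, end[i]); windows
    # running past the chromosome end or the bp-span cap are not scored
    idx0 = np.arange(m)
    end = np.minimum(idx0 + params.window_min_snps, m)
    full = end - idx0 == params.window_min_snps
    span_ok = np.zeros(m, dtype=bool)
    span_ok[full] = pos[end[full] - 1] - pos[idx0[full]] <= window_bp
    valid = full & span_ok

    het = np.concatenate([[0], np.cumsum(calls == 1)])
    mis = np.concatenate([[0], np.cumsum(calls == MISSING)])
    idx = np.arange(m)
    hom_window = (
        (het[end] - het[idx] <= params.window_max_het)
        & (mis[end] - mis[idx] <= params.window_max_missing)
        & valid
    )

    # windows spanning SNP j: starts i in [lo_j, j] with end[i] > j
    lo = np.searchsorted(end, idx + 1, side="left")
    cnt_valid = np.concatenate([[0], np.cumsum(valid)])
    cnt_hom = np.concatenate([[0], np.cumsum(hom_window)])
    n_span = cnt_valid[idx + 1] - cnt_valid[lo]
    n_hom = cnt_hom[idx + 1] - cnt_hom[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(n_span > 0, n_hom / np.maximum(n_span, 1), 0.0)
    return (n_span > 0) & (prop >= params.hit_proportion)


def _segments_from_flags(
    flags: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Candidate (start_idx, end_idx inclusive) stretches after gap splitting."""
    segs: list[tuple[int, int]] = []
    gap_bp = params.gap_split_kb * 1000.0
    start = None
    for j in range(flags.size):
        if flags[j]:
            if start is None:
                start = j
            elif pos[j] - pos[j - 1] >= gap_bp:
                segs.append((start, j - 1))
                start = j
        elif start is not None:
            segs.append((start, j - 1))
            start = None
    if start is not None:
        segs.append((start, flags.size - 1))
    return segs


def detect_roh(g: GenotypeMatrix, sample_id: str, params: ROHParams = ROHParams()) -> ROHSet:
    """Runs of homozygosity of one individual across all chromosomes."""
    try:
        i = g.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample {sample_id!r}") from None
    result = ROHSet(sample_id)
    chroms = g.chromosomes
    pos_all = g.positions
    for c in dict.fromkeys(chroms):
        sel = np.where(chroms == c)[0]
        pos = pos_all[sel]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNP positions on chromosome {c} are not sorted")
        if np.any(np.diff(pos) == 0):
            raise ValueError(f"duplicate SNP positions on chromosome {c}")
        if pos.size < params.window_min_snps:
            logger.info("chromosome %s has fewer than %d SNPs; skipped", c, params.window_min_snps)
            continue
        calls = g.calls[i, sel]
        flags = _in_segment_flags(calls, pos, params)
        for s, e in _segments_from_flags(flags, pos, params):
            n_snps = e - s + 1
            length_bp = int(pos[e] - pos[s])
            if length_bp < params.min_run_kb * 1000.0:
                continue
            if n_snps < params.min_run_snps:
                continue
            if length_bp / 1000.0 / n_snps > params.min_density_kb_per_snp:
                continue
            result.runs.append(ROHRun(str(c), int(pos[s]), int(pos[e]), n_snps))
    return result


def detect_roh_cohort(g: GenotypeMatrix, params: ROHParams = ROHParams()) -> list[ROHSet]:
    return [detect_roh(g, sid, params) for sid in g.sample_ids]


def roh_length_class_summary(
    rohsets: list[ROHSet], intervals: list[tuple[float, float]]
) -> list[float]:
    """Per length bin [lo, hi) in bp: fraction of individuals with >= 1 run in it."""
    out = []
    n = len(rohsets)
    for lo, hi in intervals:
        k = sum(
            1 for rs in rohsets if any(lo <= r.length_bp < hi for r in rs.runs)
        )
        out.append(k / n if n else 0.0)
    return out


def mean_total_roh_length(
    rohsets: list[ROHSet], min_length_grid: list[float]
) -> list[float]:
    """Mean (over individuals) total bp in runs of at least each grid length."""
    n = len(rohsets)
    return [
        (sum(rs.total_length_bp(L) for rs in rohsets) / n) if n else 0.0
        for L in min_length_grid
    ]
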