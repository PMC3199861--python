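"""Pairwise linkage disequilibrium: r, |D'|, odds ratio lambda and eta1.

Haplotype frequencies for a SNP pair are estimated from unphased genotypes
by the standard two-locus EM algorithm (only double heterozygotes are
phase-ambiguous).  From the frequencies (p_AB, p_Ab, p_aB, p_ab):

    D       = p_AB - p_A * p_B
    r       = D / sqrt(p_A p_a p_B p_b)
    D'      = D / D_max given the margins
    lambda  = (p_AB * p_ab) / (p_Ab * p_aB)      (haplotype odds ratio)

``eta1`` is an allele-frequency-free transform of lambda into [-1, 1]:
|eta1| is the probability that a haplotype-frequency vector drawn uniformly
on the 3-simplex has a less extreme |log odds ratio| than the observed one,
signed by the direction of association.  It is evaluated against a cached
Monte-Carlo quantile table of |log lambda| under the uniform Dirichlet null
(fixed seed, 10^6 draws), which makes it odd under lambda -> 1/lambda by
construction.

Decay profiles average a chosen measure in 5-kb distance bins and smooth
the bin means with a LOWESS curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "LDRecord",
    "LDProfile",
    "estimate_pair_ld",
    "em_haplotype_freqs",
    "eta1_from_odds_ratio",
    "ld_decay_profile",
]

_ETA1_TABLE_SEED = 190834127
_ETA1_TABLE_SIZE = 1_000_000
_eta1_table: np.ndarray | None = None


@dataclass(frozen=True)
class LDRecord:
    snp_i: str
    snp_j: str
    distance_bp: int
    r: float
    abs_dprime: float
    lambda_: float
    eta1: float
    converged: bool = True


@dataclass
class LDProfile:
    bin_edges_bp: np.ndarray  # half-open [edge_k, edge_{k+1})
    mean_per_bin: np.ndarray  # NaN for empty bins
    n_per_bin: np.ndarray
    smoothed: np.ndarray  # LOWESS over non-empty bin midpoints

    @property
    def midpoints_bp(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_bp[:-1] + self.bin_edges_bp[1:])


# ---------------------------------------------------------------------------
# Two-locus EM
# ---------------------------------------------------------------------------


def _genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts over complete-case individuals."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    counts = np.zeros((3, 3))
    for x in range(3):
        for y in range(3):
            counts[x, y] = np.sum(ok & (g1 == x) & (g2 == y))
    return counts


def _em_from_counts(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, bool]:
    """EM haplotype frequencies (f_ab, f_aB, f_Ab, f_AB) from a 3x3 table.

    Allele "A"/"B" denote the counted allele at each locus; index order is
    (hap allele at locus1, at locus2) with 0 = other, 1 = counted.
    Vectorized over trailing dimensions: ``counts`` may be (3, 3, P).
    """
    c = np.asarray(counts, dtype=np.float64)
    squeeze = c.ndim == 2
    if squeeze:
        c = c[:, :, None]
    n = c.sum(axis=(0, 1))
    two_n = 2.0 * n
    # known haplotype contributions; h[i,j] = count of haplotype with
    # (allele at locus 1, allele at locus 2); 1 = counted allele.
    # Every genotype except the double het resolves deterministically.
    h_known = np.zeros((2, 2) + c.shape[2:])
    contrib = {
        (0, 0): {(0, 0): 2},
        (0, 1): {(0, 0): 1, (0, 1): 1},
        (0, 2): {(0, 1): 2},
        (1, 0): {(0, 0): 1, (1, 0): 1},
        (1, 2): {(0, 1): 1, (1, 1): 1},
        (2, 0): {(1, 0): 2},
        (2, 1): {(1, 0): 1, (1, 1): 1},
        (2, 2): {(1, 1): 2},
    }
    for (x, y), haps in contrib.items():
        for (i, j), k in haps.items():
            h_known[i, j] += k * c[x, y]
    dh = c[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    f = np.full((2, 2) + c.shape[2:], 0.25)
    converged = np.zeros(c.shape[2:], dtype=bool)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            num = f[1, 1] * f[0, 0]
            den = num + f[1, 0] * f[0, 1]
            w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        h = h_known.copy()
        h[1, 1] += dh * w
        h[0, 0] += dh * w
        h[1, 0] += dh * (1.0 - w)
        h[0, 1] += dh * (1.0 - w)
        f_new = h / two_n
        delta = np.abs(f_new - f).max(axis=(0, 1))
        f = f_new
        converged = delta < tol
        if converged.all():
            break
    if squeeze:
        return f[:, :, 0], bool(converged)
    return f, converged


def em_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[dict[str, float], bool]:
    """Haplotype frequencies {AB, Ab, aB, ab} for one SNP pair ("A"/"B" = counted alleles)."""
    counts = _genotype_pair_counts(np.asarray(g1), np.asarray(g2))
    f, conv = _em_from_counts(counts, tol, max_iter)
    return {"AB": float(f[1, 1]), "Ab": float(f[1, 0]), "aB": float(f[0, 1]), "ab": float(f[0, 0])}, conv


# ---------------------------------------------------------------------------
# eta1
# ---------------------------------------------------------------------------


def _quantile_table() -> np.ndarray:
    """Sorted |log lambda| under haplotype frequencies uniform on the 3-simplex."""
    global _eta1_table
    if _eta1_table is None:
        rng = np.random.default_rng(_ETA1_TABLE_SEED)
        f = rng.dirichlet(np.ones(4), size=_ETA1_TABLE_SIZE)
        logl = np.log(f[:, 0]) + np.log(f[:, 3]) - np.log(f[:, 1]) - np.log(f[:, 2])
        _eta1_table = np.sort(np.abs(logl))
    return _eta1_table


def eta1_from_odds_ratio(lambda_: float, n_mc: int | None = None, seed: int | None = None) -> float:
    """eta1 from the haplotype odds ratio.

    |eta1| = P(|log OR| of a uniform-Dirichlet haplotype table < |log lambda|),
    signed by sign(log lambda).  With ``n_mc`` set, a fresh Monte-Carlo
    estimate with that many draws is computed instead of using the cached
    table (useful as an independent check).
    """
    if lambda_ < 0 or np.isnan(lambda_):
        raise ValueError("odds ratio must be non-negative")
    if lambda_ == 0.0:
        return -1.0
    if np.isinf(lambda_):
        return 1.0
    logl = np.log(lambda_)
    if logl == 0.0:
        return 0.0
    if n_mc is not None:
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4), size=int(n_mc))
        sample = np.abs(np.log(f[:, 0]) + np.log(f[:, 3]) - np.log(f[:, 1]) - np.log(f[:, 2]))
        frac = np.mean(sample < abs(logl))
    else:
        table = _quantile_table()
        frac = np.searchsorted(table, abs(logl), side="left") / table.size
    return float(np.sign(logl) * frac)


def _eta1_vector(lambdas: np.ndarray) -> np.ndarray:
    table = _quantile_table()
    out = np.zeros(lambdas.shape)
    with np.errstate(divide="ignore"):
        logl = np.log(lambdas)
    finite = np.isfinite(logl)
    out[finite] = np.sign(logl[finite]) * (
        np.searchsorted(table, np.abs(logl[finite]), side="left") / table.size
    )
    out[np.isinf(logl) & (logl > 0)] = 1.0
    out[np.isinf(logl) & (logl < 0)] = -1.0
    out[np.isnan(lambdas)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Pair measures and profiles
# ---------------------------------------------------------------------------


def _measures_from_freqs(f: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(r, |D'|, lambda) from haplotype frequency array (2, 2, P)."""
    pA = f[1, 1] + f[1, 0]
    pB = f[1, 1] + f[0, 1]
    D = f[1, 1] - pA * pB
    with np.errstate(divide="ignore", invalid="ignore"):
        r = D / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
        dmax = np.where(
            D >= 0,
            np.minimum(pA * (1 - pB), (1 - pA) * pB),
            np.minimum(pA * pB, (1 - pA) * (1 - pB)),
        )
        dprime = np.abs(D / dmax)
        lam = (f[1, 1] * f[0, 0]) / (f[1, 0] * f[0, 1])
    lam = np.where((f[1, 0] * f[0, 1]) == 0,
                   np.where(f[1, 1] * f[0, 0] == 0, np.nan, np.inf), lam)
    return r, dprime, lam


def estimate_pair_ld(
    g: GenotypeMatrix | None = None,
    snp_i: str | None = None,
    snp_j: str | None = None,
    *,
    g1: np.ndarray | None = None,
    g2: np.ndarray | None = None,
    min_individuals: int = 20,
) -> LDRecord:
    """LD record for one SNP pair, from a matrix + ids or raw genotype vectors."""
    if g is not None:
        ji, jj = g.snp_ids.index(snp_i), g.snp_ids.index(snp_j)
        g1 = g.calls[:, ji]
        g2 = g.calls[:, jj]
        dist = abs(g.snps[ji].position_bp - g.snps[jj].position_bp)
        name_i, name_j = snp_i, snp_j
    else:
        dist = 0
        name_i, name_j = "snp_i", "snp_j"
    assert g1 is not None and g2 is not None
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < min_individuals:
        raise ValueError("too few complete-case individuals")
    for v in (g1[ok], g2[ok]):
        if np.all(v == v[0]):
            raise ValueError("monomorphic SNP; LD undefined")
    counts = _genotype_pair_counts(g1, g2)
    f, conv = _em_from_counts(counts)
    r, dprime, lam = _measures_from_freqs(f[:, :, None])
    eta = eta1_from_odds_ratio(float(lam[0]))
    return LDRecord(name_i, name_j, int(dist), float(r[0]), float(dprime[0]),
                    float(lam[0]), eta, bool(conv))


def _pairwise_ld_arrays(
    calls: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM over many SNP pairs; returns (r, |D'|, lambda, eta1)."""
    G1 = calls[:, idx_i]
    G2 = calls[:, idx_j]
    ok = (G1 != MISSING) & (G2 != MISSING)
    counts = np.zeros((3, 3, idx_i.size))
    for x in range(3):
        ex = G1 == x
        for y in range(3):
            counts[x, y] = (ok & ex & (G2 == y)).sum(axis=0)
    f, _ = _em_from_counts(counts)
    r, dprime, lam = _measures_from_freqs(f)
    eta = _eta1_vector(lam)
    # monomorphic pairs have undefined measures
    mono = np.isnan(r)
    dprime = np.where(mono, np.nan, dprime)
    eta = np.where(mono, np.nan, eta)
    return r, dprime, lam, eta


def ld_decay_profile(
    g: GenotypeMatrix,
    chromosome: str,
    bin_kb: float = 5.0,
    measure: str = "eta1",
    max_distance_bp: int = 1_000_000,
    lowess_frac: float = 0.3,
    min_maf: float = 0.01,
    abs_measure: bool = True,
) -> LDProfile:
    """Binned and LOWESS-smoothed decay profile of one LD measure.

    All intra-chromosome SNP pairs up to ``max_distance_bp`` enter; the
    measure (``'r'``, ``'dprime'`` or ``'eta1'``) is averaged per half-open
    5-kb bin (absolute value by default) and the bin means are smoothed.
    """
    if measure not in ("r", "dprime", "eta1"):
        raise ValueError("measure must be 'r', 'dprime' or 'eta1'")
    sel = np.where(g.chromosomes == chromosome)[0]
    if sel.size < 2:
        raise ValueError(f"need at least two SNPs on chromosome {chromosome}")
    freqs = g.allele_freq()[sel]
    maf = np.minimum(freqs, 1 - freqs)
    sel = sel[maf >= min_maf]
    pos = g.positions[sel]
    order = np.argsort(pos)
    sel, pos = sel[order], pos[order]

    ii, jj = [], []
    for a in range(sel.size):
        b_hi = np.searchsorted(pos, pos[a] + max_distance_bp, side="right")
        for b in range(a + 1, b_hi):
            ii.append(a)
            jj.append(b)
    ii = np.asarray(ii, dtype=np.int64)
    jj = np.asarray(jj, dtype=np.int64)
    if ii.size == 0:
        raise ValueError("no SNP pairs within the distance limit")
    dist = pos[jj] - pos[ii]
    r, dprime, lam, eta = _pairwise_ld_arrays(g.calls, sel[ii], sel[jj])
    values = {"r": r, "dprime": dprime, "eta1": eta}[measure]
    if abs_measure:
        values = np.abs(values)

    bin_bp = bin_kb * 1000.0
    n_bins = int(np.ceil((max_distance_bp + 1) / bin_bp))
    edges = np.arange(n_bins + 1) * bin_bp
    which = np.minimum((dist // bin_bp).astype(np.int64), n_bins - 1)
    mean = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=np.int64)
    good = ~np.isnan(values)
    for k in range(n_bins):
        mask = (which == k) & good
        count[k] = mask.sum()
        if count[k]:
            mean[k] = values[mask].mean()

    mids = 0.5 * (edges[:-1] + edges[1:])
    nonempty = ~np.isnan(mean)
    smoothed = np.full(n_bins, np.nan)
    if nonempty.sum() >= 2:
        fit = sm.nonparametric.lowess(
            mean[nonempty], mids[nonempty], frac=lowess_frac, it=1, return_sorted=False
        )
        smoothed[nonempty] = fit
    return LDProfile(edges, mean, count, smoothed)
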