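"""Power of proxy-SNP association testing, with and without relatedness.

The causal model is a linear regression y = beta1 * s1 + e with beta1 = 1
and residual variance chosen so that s1 explains a fraction ``v_s`` of the
total phenotype variance.  Association is tested not at s1 but at its best
proxy s2 — the SNP within +-2 Mb with maximal |r| to s1 — mimicking how a
marker panel detects an untyped causal variant.

Conditional on genotypes, the OLS slope of y on s2 is normal with

    E[b2]   = sum((s2_i - mean(s2)) * s1_i) / S,   S = sum((s2_i - mean(s2))^2)
    Var[b2] = sigma^2 / S,                         sigma^2 = Var(s1) (1 - v_s) / v_s

so the two-sided normal test at level alpha rejects with probability

    power = Phi(-z_{1-alpha/2} + |ncp|) + Phi(-z_{1-alpha/2} - |ncp|),
    ncp = E[b2] / sqrt(Var[b2]).

Under cryptic relatedness phenotypes are correlated: y = s1 + g + e with
g ~ N(0, sigma_g^2 G), G the pairwise relatedness matrix.  A naive OLS
analysis then sees an inflated estimator variance (the sandwich
c' Sigma c / S^2 instead of sigma^2 / S), which *gains* power where the
critical value exceeds the noncentrality (stringent thresholds) and
*loses* power where it does not — overlapping normals with different
spread.  ``simulate_power_mixed`` measures this by simulation and
``variance_inflation`` reports the variance ratio directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .genotype_io import MISSING, GenotypeMatrix
from .relatedness import RelatednessMatrix

__all__ = [
    "PowerModelSpec",
    "best_proxy",
    "analytic_power",
    "simulate_power_mixed",
    "variance_inflation",
    "power_distribution",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerModelSpec:
    v_s: float = 0.02
    h2: float | None = None  # None = minimal heritability (h2 = v_s)
    alpha_grid: tuple[float, ...] = (1e-5, 1e-7)
    n_reps: int = 1000
    proxy_window_bp: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        h2 = self.v_s if self.h2 is None else self.h2
        if not (0.0 <= self.v_s <= h2 <= 1.0):
            raise ValueError("need 0 <= v_s <= h2 <= 1")

    @property
    def heritability(self) -> float:
        return self.v_s if self.h2 is None else self.h2


def best_proxy(
    g: GenotypeMatrix, causal_snp: str, window_bp: int = 2_000_000
) -> tuple[str | None, float]:
    """Id and |r| of the SNP in maximal LD with the causal SNP within the window.

    LD is the complete-case dosage correlation.  Ties break to the closer
    SNP, then the smaller id; the causal SNP itself never qualifies.
    Returns (None, nan) when no candidate lies in the window.
    """
    return _best_proxy_from_dosage(g, g.dosage(), causal_snp, window_bp)


def _best_proxy_from_dosage(
    g: GenotypeMatrix, d: np.ndarray, causal_snp: str, window_bp: int
) -> tuple[str | None, float]:
    j = g.snp_ids.index(causal_snp)
    chrom = g.snps[j].chromosome
    pos = g.snps[j].position_bp
    cand = [
        k for k in range(g.n_snps)
        if k != j and g.snps[k].chromosome == chrom
        and abs(g.snps[k].position_bp - pos) <= window_bp
    ]
    if not cand:
        return None, float("nan")
    s1 = d[:, j]
    best: tuple[float, int, str, int] | None = None  # (-|r|, distance, id, k)
    for k in cand:
        s2 = d[:, k]
        ok = ~np.isnan(s1) & ~np.isnan(s2)
        a, b = s1[ok], s2[ok]
        if a.std() == 0 or b.std() == 0:
            continue
        rr = abs(float(np.corrcoef(a, b)[0, 1]))
        key = (-round(rr, 12), abs(g.snps[k].position_bp - pos), g.snps[k].snp_id, k)
        if best is None or key < best:
            best = key
    if best is None:
        return None, float("nan")
    return best[2], -best[0]


def _centered(s: np.ndarray) -> np.ndarray:
    return s - s.mean()


def analytic_power(
    s1: np.ndarray, s2: np.ndarray, v_s: float, alpha: float
) -> float:
    """Power of the two-sided normal test on the proxy slope, uncorrelated model."""
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    if s2.std() == 0:
        raise ValueError("proxy SNP is constant")
    if v_s <= 0.0:
        return alpha
    if v_s >= 1.0:
        v_s = 1.0 - 1e-12
    c = _centered(s2)
    S = float(c @ c)
    mean_b2 = float(c @ s1) / S
    var_s1 = float(np.var(s1))
    sigma2 = var_s1 * (1.0 - v_s) / v_s
    var_b2 = sigma2 / S
    ncp = abs(mean_b2) / np.sqrt(var_b2)
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(-z + ncp) + norm.cdf(-z - ncp))


def _psd_relatedness(G: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues so the mixed-model covariance is valid."""
    evals, evecs = np.linalg.eigh(G)
    if evals.min() < -1e-10:
        logger.info("relatedness matrix clipped: min eigenvalue %.3g", evals.min())
    evals = np.maximum(evals, 0.0)
    return (evecs * evals[None, :]) @ evecs.T


def _mixed_draws(
    s1: np.ndarray, G: np.ndarray, spec: PowerModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """n_reps phenotype vectors from y = s1 + g + e (columns are draws)."""
    n = s1.size
    var_s1 = float(np.var(s1))
    v_s, h2 = spec.v_s, spec.heritability
    v_total = var_s1 / v_s if v_s > 0 else 1.0
    mean_diag = float(np.trace(G) / n)
    sigma_g2 = (h2 - v_s) * v_total / mean_diag if h2 > v_s else 0.0
    sigma_e2 = (1.0 - h2) * v_total
    y = np.tile(s1[:, None], (1, spec.n_reps)).astype(np.float64)
    if sigma_g2 > 0:
        Gp = _psd_relatedness(G)
        L = np.linalg.cholesky(Gp + 1e-12 * np.eye(n))
        y += np.sqrt(sigma_g2) * (L @ rng.standard_normal((n, spec.n_reps)))
    if sigma_e2 > 0:
        y += np.sqrt(sigma_e2) * rng.standard_normal((n, spec.n_reps))
    return y


def _naive_ols_z(s2: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Wald z of the naive OLS slope of each y column on s2 (with intercept)."""
    n = s2.size
    c = _centered(s2)
    S = float(c @ c)
    b = (c @ y) / S
    yc = y - y.mean(axis=0, keepdims=True)
    rss = (yc**2).sum(axis=0) - b**2 * S
    sigma2_hat = rss / (n - 2)
    return b / np.sqrt(sigma2_hat / S)


def simulate_power_mixed(
    s1: np.ndarray, s2: np.ndarray, G: RelatednessMatrix | np.ndarray, spec: PowerModelSpec
) -> dict[float, float]:
    """Simulated power per alpha of the naive proxy analysis under the mixed model."""
    Gm = G.entries if isinstance(G, RelatednessMatrix) else np.asarray(G)
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    y = _mixed_draws(s1, Gm, spec, rng)
    z = _naive_ols_z(s2, y)
    out = {}
    for alpha in spec.alpha_grid:
        crit = norm.ppf(1.0 - alpha / 2.0)
        out[alpha] = float(np.mean(np.abs(z) > crit))
    return out


def variance_inflation(
    s2: np.ndarray, G: RelatednessMatrix | np.ndarray, spec: PowerModelSpec,
    s1: np.ndarray | None = None,
) -> tuple[float, float]:
    """(ratio, MC standard error) of empirical vs analytic slope variance.

    Empirical: variance of the naive OLS slope over ``n_reps`` mixed-model
    draws.  Analytic: sigma^2 / S with sigma^2 the total residual variance
    of the uncorrelated model, (1 - v_s) * V_total.
    """
    Gm = G.entries if isinstance(G, RelatednessMatrix) else np.asarray(G)
    s2 = np.asarray(s2, dtype=np.float64)
    s1 = s2 if s1 is None else np.asarray(s1, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    y = _mixed_draws(s1, Gm, spec, rng)
    c = _centered(s2)
    S = float(c @ c)
    b = (c @ y) / S
    emp_var = float(np.var(b, ddof=1))
    var_s1 = float(np.var(s1))
    v_total = var_s1 / spec.v_s if spec.v_s > 0 else 1.0
    analytic_var = (1.0 - spec.v_s) * v_total / S
    ratio = emp_var / analytic_var
    # SE of a variance ratio from the chi^2 approximation
    se = ratio * np.sqrt(2.0 / (spec.n_reps - 1))
    return ratio, float(se)


def power_distribution(
    g: GenotypeMatrix,
    chromosome: str,
    spec: PowerModelSpec,
    mode: str = "analytic",
    G: RelatednessMatrix | np.ndarray | None = None,
    causal_snps: list[str] | None = None,
) -> dict[float, dict[str, float]]:
    """Quartiles of per-SNP proxy power over one chromosome.

    Every polymorphic SNP acts once as the causal variant, tested through
    its best proxy.  Returns, per alpha, the quartiles of the power
    distribution and the number of SNPs without any proxy.
    """
    if mode not in ("analytic", "mixed"):
        raise ValueError("mode must be 'analytic' or 'mixed'")
    if mode == "mixed" and G is None:
        raise ValueError("mixed mode requires a relatedness matrix")
    sel = [j for j in range(g.n_snps) if g.snps[j].chromosome == chromosome]
    if causal_snps is not None:
        wanted = set(causal_snps)
        sel = [j for j in sel if g.snps[j].snp_id in wanted]
    if not sel:
        raise ValueError(f"no SNPs on chromosome {chromosome}")
    d = g.dosage()
    snp_index = {sid: k for k, sid in enumerate(g.snp_ids)}
    powers: dict[float, list[float]] = {a: [] for a in spec.alpha_grid}
    no_proxy = 0
    for j in sel:
        s1 = d[:, j]
        if np.nanstd(s1) == 0:
            continue
        proxy, _ = _best_proxy_from_dosage(g, d, g.snps[j].snp_id, spec.proxy_window_bp)
        if proxy is None:
            no_proxy += 1
            continue
        k = snp_index[proxy]
        s2 = d[:, k]
        ok = ~np.isnan(s1) & ~np.isnan(s2)
        s1c, s2c = s1[ok], s2[ok]
        if mode == "analytic":
            for alpha in spec.alpha_grid:
                powers[alpha].append(analytic_power(s1c, s2c, spec.v_s, alpha))
        else:
            Gm = G.entries if isinstance(G, RelatednessMatrix) else np.asarray(G)
            sub_spec = PowerModelSpec(
                v_s=spec.v_s, h2=spec.h2, alpha_grid=spec.alpha_grid,
                n_reps=spec.n_reps, proxy_window_bp=spec.proxy_window_bp,
                seed=(spec.seed * 1_000_003 + j) % (2**31),
            )
            sim = simulate_power_mixed(s1c, s2c, Gm[np.ix_(np.where(ok)[0], np.where(ok)[0])], sub_spec)
            for alpha in spec.alpha_grid:
                powers[alpha].append(sim[alpha])
    out: dict[float, dict[str, float]] = {}
    for alpha, vals in powers.items():
        arr = np.array(vals)
        q1, med, q3 = np.percentile(arr, [25, 50, 75]) if arr.size else (np.nan,) * 3
        out[alpha] = {
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "n_snps": int(arr.size), "n_no_proxy": no_proxy,
        }
    return out
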