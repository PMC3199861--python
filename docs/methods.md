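# Methods

This note documents the statistical models behind `isopop`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish about real cohorts.

## Data model

Genotypes are counts of a designated allele (`allele_b`) in {0, 1, 2} with
a distinct missing sentinel that never enters arithmetic; numeric work goes
through a float dosage view with NaN at missing cells.  Positions are
1-based bp, as in bim/VCF.  PLINK binary (SNP-major v1) and biallelic
GT-only VCF round-trip bit-exactly; the fam family-ID column carries the
population label, so platform/group metadata do not survive a PLINK round
trip and must be re-attached by the caller when needed.

## Synthetic cohorts

The generator produces the joint structure the analyses assume, with
ground truth recorded for every run:

* **Divergence.** Balding-Nichols: population allele frequency
  `p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)` around an ancestral `p` drawn
  uniformly on `maf_range`.  `divergence_fst` applies the same F to both
  populations; `pop_fst = (F1, F2)` drifts them asymmetrically, which is
  how an isolate acquires a rare-variant excess while the pairwise
  Weir-Cockerham F_ST stays near (F1+F2)/2.
* **LD.** A Gaussian-copula AR(1) haplotype process: a latent standard
  normal with autocorrelation `exp(-d / ld_decay_bp)` between adjacent
  SNPs, thresholded at `Phi^{-1}(p)`.  Marginal frequencies are exact;
  pairwise haplotype association decays smoothly with distance.  This is a
  first-order stand-in: it produces no block structure, no recombination
  hotspots and no allele-frequency-dependent LD, so LD-profile tests
  establish shape recovery, not realism.
* **Families.** Offspring are built by Mendelian transmission of phased
  parental haplotypes with crossovers at exponential spacings
  (`recomb_rate_per_bp`, default 1e-7).  The default is deliberately 10x
  the human per-bp rate: the toy genome is physically compressed (~10 kb
  SNP spacing, tens of Mb per chromosome), and this keeps the *genetic*
  map at tens of Morgans so realized relatedness fluctuates around
  pedigree expectations (0.5 / 0.25 / 0.125 for degrees 1-3) with
  genome-wide-like variance.  Expected relationship matrices come from the
  tabular (recursive) method and include inbreeding (a first-cousin
  offspring has diagonal 1 + 1/16).
* **Artifacts.** Per-platform missingness is Bernoulli per cell; platform
  frequency shifts re-draw one platform's genotypes from HWE at a shifted
  frequency.  Detectability of a shift of 0.3 with ~200 samples per
  platform at p < 1e-7 is ~98% (z ~ 8), which is the regime the
  artifact-recovery tests use; a 0.15 shift at that size is essentially
  undetectable at that threshold and is not a meaningful test condition.

## Quality control

The stratified HWE statistic sums signed heterozygote deficits
`d_s = O_het,s - E_het,s` over strata and refers
`Z = (|sum d_s| - 1) / sqrt(sum Var_s)` to a standard normal.  Mean and
variance are the exact conditional moments of the het count given the
stratum allele count under random pairing of alleles
(`E[h|a] = a(2n-a)/(2n-1)`, variance from `E[h(h-1)]`), so the statistic is
finite-sample corrected; the continuity correction of 1 (the het count
steps by 2 at fixed allele count) keeps the far tail honest — without it
the p < 1e-6 rate on null data is ~2e-5 instead of ~3e-6.  Summation of
deficits across strata makes the test insensitive to the Wahlund effect
that inflates any pooled test.  The platform test uses the 2x2 allele-count
table (chi-square; Fisher's exact when an expected cell is below 5).
Filters remove the *union* of failing SNPs.

## Relatedness

The estimator standardizes dosages by in-sample frequency
(`MAF >= 0.01` SNPs, complete pairs) and averages products.  It carries a
finite-sample bias of order -2/n from estimating frequencies in-sample
(~0.48 instead of 0.50 for a parent-offspring pair at n = 200); tests use
bands that accommodate it.  Unrelated-subset selection is the greedy
removal heuristic with deterministic tie-breaks (more over-cutoff
partners first, then larger maximum relatedness, then smaller id); it is
not guaranteed optimal, and a property test bounds its gap to the
exhaustive optimum on small instances.  Pair-count odds ratios are sample
ORs with Woolf intervals; the conditional-MLE OR (`method="cmle"`) is also
exposed since table rounding conventions differ between the two.

## F-statistics

Weir-Cockerham two-allele components per SNP with per-SNP complete-case
sample sizes; combination is strictly ratio-of-sums.  Jackknife SEs delete
one individual at a time (from its own population only) and recompute the
ratio from cached per-population allele/heterozygote counts, which makes
the full jackknife O(n x m) and *exactly* equal to brute-force
recomputation.  Against the true Monte-Carlo sampling SD (individuals
re-drawn at fixed population frequencies) the jackknife SE is within ~30%
on a 20+20 cohort.  Case-resampling bootstrap is deliberately not used as
a reference: duplicated individuals act as monozygotic twins and inflate
theta variability about threefold at that size.

## Runs of homozygosity

The scanning window is **50 SNPs** (anchored at each SNP, running
forward), with `window_kb = 5000` acting as a span cap for sparse regions;
windows crossing the chromosome end or the cap are not scored.  A bp-span
window of fixed 5 Mb cannot be homozygous inside any run shorter than
itself, which would make the entire 0.5-5 Mb range — the object of the
length-class summaries and of the 500-kb minimum run — undetectable; the
SNP-count reading is also how the tool that popularized this
parameterization behaves.  A window is homozygous with <= 1 heterozygote
and <= 5 missing calls; a SNP is in a segment when >= 5% of its scored
spanning windows are homozygous; segments split at >= 100 kb gaps and are
reported at >= 500 kb, >= 100 SNPs, >= 1 SNP / 50 kb.  Run length is
last-SNP minus first-SNP position; a heterozygote can survive inside a
reported run (voting, not post-filtering).  The caller is pinned to a
direct-enumeration oracle on 100 random fixtures.

## Linkage disequilibrium

Haplotype frequencies come from the standard two-locus EM on unphased
complete-case genotypes (only the double heterozygote is ambiguous;
tolerance 1e-10, 1000 iterations, vectorized across pairs).  From the
frequencies: `D`, `r`, `|D'|`, and the odds ratio
`lambda = p_AB p_ab / (p_Ab p_aB)`.  **eta1** is defined operationally:
`|eta1|` is the probability that a haplotype table drawn uniformly on the
3-simplex (Dirichlet(1,1,1,1)) has `|log OR|` smaller than the observed
`|log lambda|`, signed by `sign(log lambda)`.  It is evaluated against a
cached sorted table of 1e6 fixed-seed draws, which makes `eta1(1/l) =
-eta1(l)` exact by construction and the measure free of allele
frequencies; an independent fresh-Monte-Carlo estimate is the test oracle.
"Less extreme LD" is read on the |log odds ratio| scale.  Profiles average
a measure in half-open 5-kb bins and smooth bin means with LOWESS
(span 0.3, one robustness iteration; the span is a package choice and is
configurable).  Null |eta1| is biased upward at smaller n (fewer samples
push the estimated table toward extremes), reproducing the known
sample-size bias of LD comparisons.

## PCA

Standardization is `(x - 2p)/sqrt(p(1-p))` with mean imputation of
missing; each SNP is residualized on its two predecessors on the same
chromosome; the individual covariance is eigendecomposed; individuals
beyond 6 SD on any of the top 10 components are dropped and the
decomposition repeated (<= 5 iterations), with frequencies recomputed per
iteration.  Components are oriented so the largest-magnitude SNP loading
is positive.  On LD-free data the LD correction is only *nearly* inert:
residualizing on independent predecessors injects O(n^{-1/2}) coefficient
noise, so leading scores correlate at ~0.99, not to machine precision.

## Power under proxy testing

With `beta1 = 1` and residual variance `Var(s1)(1-v_s)/v_s`, the OLS slope
on the proxy is conditionally normal with mean `c's1/S` and variance
`sigma^2/S` (`c` the centered proxy, `S = c'c`); power of the two-sided
normal test is `Phi(-z + |ncp|) + Phi(-z - |ncp|)`.  The derivation was
re-established and validated against an OLS Monte-Carlo oracle over a
(v_s, alpha) grid before anything was built on it.  The mixed model scales
the polygenic variance by the mean diagonal of G
(`sigma_g^2 = (h2 - v_s) V_total / mean(diag G)`,
`sigma_e^2 = (1 - h2) V_total`, `V_total = Var(s1)/v_s`), so `h2 = v_s`
reduces exactly to the analytic case and G = I at any h2 reduces to it
too.  The naive analysis estimates its residual variance from residuals —
precisely the mis-calibration relatedness induces.  Variance inflation is
the empirical slope variance over draws divided by `sigma^2/S`; for sib
blocks with duplicated genotypes at h2 = 1 the sandwich form gives exactly
1.5.  Consequence for power: the inflated-variance test gains power where
the critical value exceeds the noncentrality (stringent thresholds) and
loses it where it does not — two overlapping normals with different
spreads.  The two-sided normal (not t) reference is used throughout; at
the sample sizes involved (n >= 400 in every simulation) the difference is
far below Monte-Carlo resolution.

## Pipeline and problem sizes

`run_study` chains simulation/loading, QC, relatedness (with the matched
subset design: full isolate vs an equal random subset of unrelated outbred
individuals; unrelated isolate vs an equal random subset of that), rare
variants, F-statistics, ROH, LD profiles and analytic power quartiles, all
from one seed.  Default report sizes are deliberately modest — hundreds of
individuals, a few thousand SNPs, power quartiles on a subsample of causal
SNPs (`power_max_snps`) — chosen so a complete study and its tests run in
minutes while every qualitative contrast (relatedness excess, rare-SNP
excess, positive F_ST, long-range LD elevation, intermediate-ROH excess)
remains resolvable.  The mixed-mode power path over a whole chromosome is
available but not part of the default report for the same reason.

## Known limitations

* The simulator has no demographic history, selection, or X chromosome;
  platform artifacts are frequency shifts and missingness only.
* The relatedness estimator's -2/n in-sample-frequency bias is not
  corrected; it is documented and absorbed by test bands.
* The greedy unrelated-subset algorithm is a heuristic, as in the
  procedure it mirrors.
* eta1's published closed form is not reproduced here; the percentile
  definition under the uniform haplotype null is the operative one, and
  the Monte-Carlo table (1e6 draws) limits its resolution to ~1e-3.
* PLINK round trips drop platform/group sample metadata (fam has no
  columns for them).
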