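"""End-to-end study orchestration: cohorts -> QC -> all comparisons.

``run_study`` reproduces the analysis sequence of an isolate-vs-outbred
comparison: quality control, relatedness structure and unrelated-subset
construction, size-matched cohort subsets, rare-SNP excess, F-statistics,
ROH summaries, LD decay profiles and proxy-SNP power quartiles.  Cohorts
are either loaded from disk or simulated; all randomness derives from the
study seed, so a config runs to an identical report every time.

Subset matching follows the comparison design: the complete isolate sample
is matched against an equally sized random subset of *unrelated* outbred
individuals, and the unrelated-isolate subset against an equally sized
random subset of that matched outbred sample.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import fstatistics, ld, qc, rare_variants, relatedness, roh
from .genotype_io import GenotypeMatrix, load_genotypes
from .power import PowerModelSpec, power_distribution
from .synthetic_data import SimConfig, inject_artifacts, simulate_two_populations

__all__ = ["StudyConfig", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    sim: SimConfig | None = None
    input_path: str | None = None
    input_format: str = "plink-bed"
    isolate_label: str = "pop1"
    outbred_label: str = "pop2"
    thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    relatedness_cutoff: float = 0.2
    sensitivity_cutoff: float | None = None  # e.g. 0.1
    pair_bounds: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6)
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    ld_chromosome: str = "1"
    ld_measure: str = "eta1"
    ld_max_distance_bp: int = 500_000
    power_spec: PowerModelSpec = field(default_factory=PowerModelSpec)
    power_max_snps: int | None = 200  # subsample causal SNPs for the quartiles
    roh_bins_mb: tuple[tuple[float, float], ...] = (
        (0.5, 1.0), (1.0, 2.5), (2.5, 5.0), (5.0, np.inf),
    )
    analyses: tuple[str, ...] = (
        "relatedness", "rare", "fstats", "roh", "ld", "power",
    )
    seed: int = 0
    output_dir: str | None = None


def _match_subset(ids: list[str], n: int, rng: np.random.Generator) -> list[str]:
    if len(ids) < n:
        raise ValueError(f"cannot match subset of {n} from {len(ids)} individuals")
    pick = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(pick)]


def run_study(cfg: StudyConfig) -> dict[str, Any]:
    """Run the full comparison; returns a nested, JSON-serializable report."""
    rng = np.random.default_rng(cfg.seed)
    report: dict[str, Any] = {"seed": cfg.seed}

    if cfg.sim is not None:
        g, truth = simulate_two_populations(cfg.sim)
        if cfg.sim.missing_rate_by_platform or cfg.sim.platform_shift_snps[0]:
            g, artifact_ids = inject_artifacts(g, cfg.sim)
            truth.artifact_snps = artifact_ids
        report["truth_artifact_snps"] = len(truth.artifact_snps)
    elif cfg.input_path is not None:
        g = load_genotypes(cfg.input_path, cfg.input_format)
    else:
        raise ValueError("StudyConfig needs either sim or input_path")
    logger.info("input: %d samples x %d SNPs", g.n_samples, g.n_snps)

    g_qc, qc_report = qc.apply_qc(g, cfg.thresholds)
    report["qc"] = qc_report.summary()
    logger.info("QC retained %d of %d SNPs", qc_report.n_retained, qc_report.n_input)

    iso_idx = g_qc.samples_by_population(cfg.isolate_label)
    out_idx = g_qc.samples_by_population(cfg.outbred_label)
    g_iso = g_qc.subset_samples(iso_idx)
    g_out = g_qc.subset_samples(out_idx)

    R_iso = relatedness.estimate_relatedness(g_iso)
    R_out = relatedness.estimate_relatedness(g_out)

    if "relatedness" in cfg.analyses:
        dist_iso = relatedness.pair_distribution(R_iso, list(cfg.pair_bounds))
        dist_out = relatedness.pair_distribution(R_out, list(cfg.pair_bounds))
        ors = {}
        for b, ci, co in zip(dist_iso.lower_bounds, dist_iso.counts, dist_out.counts):
            if co > 0:
                or_, ci95 = relatedness.related_pair_odds_ratio(
                    ci, dist_iso.total_pairs, co, dist_out.total_pairs
                )
            else:
                or_, ci95 = float("inf"), (float("nan"), float("inf"))
            ors[b] = {"isolate_pairs": ci, "outbred_pairs": co,
                      "odds_ratio": or_, "ci95": list(ci95)}
        report["relatedness"] = {
            "total_pairs_isolate": dist_iso.total_pairs,
            "total_pairs_outbred": dist_out.total_pairs,
            "pair_distribution": ors,
        }

    unrel_iso = relatedness.select_unrelated(R_iso, cfg.relatedness_cutoff)
    unrel_out = relatedness.select_unrelated(R_out, cfg.relatedness_cutoff)
    report.setdefault("subsets", {})
    report["subsets"].update({
        "n_isolate": len(iso_idx), "n_outbred": len(out_idx),
        "n_unrelated_isolate": len(unrel_iso), "n_unrelated_outbred": len(unrel_out),
    })
    if cfg.sensitivity_cutoff is not None:
        report["subsets"]["n_unrelated_isolate_sensitivity"] = len(
            relatedness.select_unrelated(R_iso, cfg.sensitivity_cutoff)
        )

    # matched subsets: full isolate vs random unrelated outbred of equal size;
    # unrelated isolate vs random subset of the matched outbred sample
    n_full = g_iso.n_samples
    matched_out_full = _match_subset(unrel_out, min(n_full, len(unrel_out)), rng)
    n_unrel = len(unrel_iso)
    matched_out_unrel = _match_subset(matched_out_full, min(n_unrel, len(matched_out_full)), rng)

    cohorts = {
        "isolate_full": g_iso,
        "outbred_matched_full": g_out.select_sample_ids(matched_out_full),
        "isolate_unrelated": g_iso.select_sample_ids(unrel_iso),
        "outbred_matched_unrelated": g_out.select_sample_ids(matched_out_unrel),
    }

    if "rare" in cfg.analyses:
        rare: dict[str, Any] = {}
        for name, gg in cohorts.items():
            _, count = rare_variants.classify_rare(gg)
            rare[name] = count
        or_full, p_full = rare_variants.compare_rare_odds(
            rare["isolate_full"], g_qc.n_snps, rare["outbred_matched_full"]
        )
        rare["odds_ratio_full"] = or_full
        rare["fisher_p_full"] = p_full
        report["rare_snps"] = rare

    if "fstats" in cfg.analyses:
        fstat: dict[str, Any] = {}
        for name, gg in cohorts.items():
            res = fstatistics.fis(gg)
            fstat[f"fis_{name}"] = {"estimate": res.estimate, "se": res.se}
        for tag, (ga, gb) in {
            "full": (cohorts["isolate_full"], cohorts["outbred_matched_full"]),
            "unrelated": (cohorts["isolate_unrelated"], cohorts["outbred_matched_unrelated"]),
        }.items():
            merged = GenotypeMatrix(
                list(ga.samples) + list(gb.samples),
                list(ga.snps),
                np.vstack([ga.calls, gb.calls]),
            )
            res = fstatistics.fst(merged, cfg.isolate_label, cfg.outbred_label)
            fstat[f"fst_{tag}"] = {"estimate": res.estimate, "se": res.se}
        report["fstatistics"] = fstat

    if "roh" in cfg.analyses:
        bins_bp = [(lo * 1e6, hi * 1e6) for lo, hi in cfg.roh_bins_mb]
        grid = [b[0] for b in bins_bp]
        roh_report: dict[str, Any] = {"bins_mb": [list(b) for b in cfg.roh_bins_mb]}
        for name in ("isolate_full", "outbred_matched_full"):
            sets = roh.detect_roh_cohort(cohorts[name], cfg.roh_params)
            roh_report[name] = {
                "prop_with_roh_per_bin": roh.roh_length_class_summary(sets, bins_bp),
                "mean_total_length_bp": roh.mean_total_roh_length(sets, grid),
                "n_runs": sum(len(s.runs) for s in sets),
            }
        report["roh"] = roh_report

    if "ld" in cfg.analyses:
        ld_report: dict[str, Any] = {"measure": cfg.ld_measure,
                                     "chromosome": cfg.ld_chromosome}
        for name, gg in cohorts.items():
            prof = ld.ld_decay_profile(
                gg, cfg.ld_chromosome, measure=cfg.ld_measure,
                max_distance_bp=cfg.ld_max_distance_bp,
            )
            ld_report[name] = {
                "bin_mid_bp": prof.midpoints_bp.tolist(),
                "mean": [None if np.isnan(v) else float(v) for v in prof.mean_per_bin],
                "smoothed": [None if np.isnan(v) else float(v) for v in prof.smoothed],
            }
        report["ld"] = ld_report

    if "power" in cfg.analyses:
        pw: dict[str, Any] = {"v_s": cfg.power_spec.v_s,
                              "alpha_grid": list(cfg.power_spec.alpha_grid)}
        chrom_snps = [s.snp_id for s in g_qc.snps if s.chromosome == cfg.ld_chromosome]
        causal = None
        if cfg.power_max_snps is not None and len(chrom_snps) > cfg.power_max_snps:
            pick = rng.choice(len(chrom_snps), size=cfg.power_max_snps, replace=False)
            causal = [chrom_snps[i] for i in sorted(pick)]
        for name in ("isolate_full", "outbred_matched_full"):
            res = power_distribution(
                cohorts[name], cfg.ld_chromosome, cfg.power_spec, mode="analytic",
                causal_snps=causal,
            )
            pw[name] = {str(a): q for a, q in res.items()}
        report["power"] = pw

    if cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")
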