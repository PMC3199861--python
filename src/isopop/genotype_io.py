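"""Genotype data model and PLINK/VCF readers and writers.

The central container is :class:`GenotypeMatrix`: an individuals x SNPs
matrix of counts of ``allele_b`` (0/1/2) with a distinct missing sentinel,
plus per-SNP map information and per-sample metadata.  Every downstream
statistic (relatedness, F-statistics, ROH, LD, power) operates on this
object.

Supported on-disk formats:

* PLINK binary (``.bed``/``.bim``/``.fam``), SNP-major, v1 magic bytes.
  ``allele_a`` maps to the bim A1 column and ``allele_b`` to A2, so a
  genotype of 2 means homozygous A2.  The fam family-ID column carries the
  population label (a common convention for multi-cohort panels); platform
  and group labels do not survive a PLINK round trip.
* VCF (v4.x, GT only, biallelic SNPs).  ``allele_b`` is the ALT allele.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "SnpMeta",
    "SampleMeta",
    "GenotypeMatrix",
    "load_genotypes",
    "save_genotypes",
    "GenotypeParseError",
]

#: Sentinel for a missing genotype call.  Kept out of dosage arithmetic:
#: use :meth:`GenotypeMatrix.dosage` (NaN for missing) for numeric work.
MISSING: int = -9

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> allele_b count; 01 is the missing code.
_BED_CODE_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_BED_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


class GenotypeParseError(ValueError):
    """Raised when an input file is malformed or internally inconsistent."""


@dataclass(frozen=True)
class SnpMeta:
    """Map entry for one SNP (1-based bp position, as in bim/VCF)."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    population: str = "pop1"
    platform: str | None = None
    group: str | None = None
    sex: str | None = None


@dataclass
class GenotypeMatrix:
    """Cohort genotypes: ``calls[i, j]`` counts allele_b of sample i at SNP j."""

    samples: list[SampleMeta]
    snps: list[SnpMeta]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.calls, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        sids = [s.snp_id for s in self.snps]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate SNP ids")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosage(self) -> np.ndarray:
        """Calls as float with NaN at missing cells."""
        d = self.calls.astype(np.float64)
        d[self.calls == MISSING] = np.nan
        return d

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of allele_b among called genotypes (NaN if none)."""
        d = self.dosage()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index], list(self.snps), self.calls[index, :]
        )

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            list(self.samples), [self.snps[j] for j in index], self.calls[:, index]
        )

    def samples_by_population(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.population == population],
            dtype=np.int64,
        )

    def select_sample_ids(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(ids)
        idx = [i for i, s in enumerate(self.samples) if s.sample_id in wanted]
        return self.subset_samples(idx)

    def sort_map(self) -> "GenotypeMatrix":
        """Return a copy with SNPs sorted by (chromosome, position)."""
        order = sorted(
            range(self.n_snps),
            key=lambda j: (self.snps[j].chromosome, self.snps[j].position_bp),
        )
        return self.subset_snps(order)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and [(s.snp_id, s.chromosome, s.position_bp, s.allele_a, s.allele_b)
                 for s in self.snps]
            == [(s.snp_id, s.chromosome, s.position_bp, s.allele_a, s.allele_b)
                for s in other.snps]
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


def _read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = str(prefix)
    bim_path, fam_path, bed_path = prefix + ".bim", prefix + ".fam", prefix + ".bed"
    for p in (bed_path, bim_path, fam_path):
        if not os.path.exists(p):
            raise GenotypeParseError(f"missing file: {p}")

    snps: list[SnpMeta] = []
    with open(bim_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise GenotypeParseError(f"{bim_path}:{lineno}: expected 6 columns")
            chrom, snp_id, _cm, pos, a1, a2 = parts
            snps.append(SnpMeta(snp_id, chrom, int(pos), a1, a2))

    samples: list[SampleMeta] = []
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise GenotypeParseError(f"{fam_path}:{lineno}: expected 6 columns")
            fid, iid, _pat, _mat, sex, _phe = parts
            samples.append(
                SampleMeta(iid, population=fid, sex={"1": "M", "2": "F"}.get(sex))
            )

    n, m = len(samples), len(snps)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeParseError(f"{bed_path}: bad magic bytes (not SNP-major bed v1)")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * m:
        raise GenotypeParseError(
            f"{bed_path}: size {body.size} does not match {n} samples x {m} SNPs"
        )
    # expand each byte into four 2-bit codes (low bits = first sample)
    if m == 0 or n == 0:
        return GenotypeMatrix(samples, snps, np.zeros((n, m), dtype=np.int8))
    mat = body.reshape(m, bytes_per_snp)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (mat[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _BED_CODE_TO_CALL[codes].T.copy()
    return GenotypeMatrix(samples, snps, calls)


def _write_plink(g: GenotypeMatrix, prefix: str | Path) -> list[str]:
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    with open(prefix + ".bim", "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t{s.allele_a}\t{s.allele_b}\n")
    with open(prefix + ".fam", "w") as fh:
        for s in g.samples:
            sex = {"M": "1", "F": "2"}.get(s.sex or "", "0")
            fh.write(f"{s.population}\t{s.sample_id}\t0\t0\t{sex}\t-9\n")
    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        if m and bytes_per_snp:
            code_lut = np.zeros(256, dtype=np.uint8)
            for call, code in _CALL_TO_BED_CODE.items():
                code_lut[np.int8(call).view(np.uint8)] = code
            codes = code_lut[g.calls.T.astype(np.uint8)]  # m x n
            padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
            padded[:, :n] = codes
            packed = (
                padded.reshape(m, bytes_per_snp, 4)
                << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
            ).sum(axis=2, dtype=np.uint8)
            fh.write(packed.tobytes())
    return [prefix + ext for ext in (".bed", ".bim", ".fam")]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    path = str(path)
    if not os.path.exists(path):
        raise GenotypeParseError(f"missing file: {path}")
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = [SampleMeta(sid) for sid in vcf.samples]
    snps: list[SnpMeta] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} is not biallelic"
            )
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snps.append(
            SnpMeta(snp_id, variant.CHROM, variant.POS, variant.REF, variant.ALT[0])
        )
        gt = np.asarray(variant.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, snps, calls)


def _write_vcf(g: GenotypeMatrix, path: str | Path) -> list[str]:
    path = str(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(s.chromosome for s in g.snps)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + g.sample_ids)
        fh.write(cols + "\n")
        for j, s in enumerate(g.snps):
            gts = "\t".join(gt_str[int(c)] for c in g.calls[:, j])
            fh.write(f"{s.chromosome}\t{s.position_bp}\t{s.snp_id}\t{s.allele_a}\t{s.allele_b}\t.\t.\t.\tGT\t{gts}\n")
    return [path]


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def load_genotypes(path: str | Path, format: str = "plink-bed") -> GenotypeMatrix:
    """Load genotypes from ``path`` (a PLINK prefix or a VCF file)."""
    if format == "plink-bed":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def save_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "plink-bed") -> list[str]:
    """Write ``g`` to disk; ``load_genotypes`` of the result round-trips."""
    if format == "plink-bed":
        return _write_plink(g, path)
    if format == "vcf":
        return _write_vcf(g, path)
    raise ValueError(f"unknown format {format!r}")
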