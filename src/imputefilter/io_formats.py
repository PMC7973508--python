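"""Core containers and readers/writers for the standard file formats.

Formats covered: Oxford GEN/SAMPLE (IMPUTE2 dialect), IMPUTE-style
.hap/.legend, VCF 4.2 with GT/GP/DS, TSV minor-allele-frequency tables
and YAML configs.  Coordinates are 1-based inclusive everywhere; no
reader or writer re-bases.

Variant identity is keyed on (chrom, pos, sorted alleles); the rsid
column is decorative.  This deliberately allows two distinct records at
one position (e.g. a SNP and a structural variant), the "dual
imputation" case handled downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1  # hard-genotype missing code

__all__ = [
    "MISSING",
    "VariantClass",
    "VariantRecord",
    "HaplotypePanel",
    "GenotypeMatrix",
    "GenotypeProbabilities",
    "FormatError",
    "read_gen",
    "write_gen",
    "read_hap_legend",
    "write_hap_legend",
    "read_vcf_gp",
    "write_vcf",
    "read_maf_table",
    "write_maf_table",
]


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


class VariantClass(str, Enum):
    SNP = "snp"
    STRUCTURAL = "structural"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant.

    ``pos`` is 1-based.  ``source`` distinguishes array-typed variants
    from variants only present in the imputation output.
    """

    id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    variant_class: VariantClass = VariantClass.SNP
    source: str = "imputed_only"  # "typed" | "imputed_only"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.allele_a or not self.allele_b:
            raise ValueError("allele strings must be nonempty")

    @property
    def key(self) -> tuple[str, int, tuple[str, str]]:
        """Identity key: (chrom, pos, sorted alleles)."""
        return (self.chrom, self.pos, tuple(sorted((self.allele_a, self.allele_b))))


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with site metadata.

    ``haplotypes`` has shape (n_haplotypes, n_sites), values in {0, 1}.
    Consecutive haplotype pairs (2i, 2i+1) form individual i when the
    panel represents a diploid cohort.
    """

    positions: np.ndarray  # int64, 1-based, strictly increasing
    haplotypes: np.ndarray  # uint8 (n_hap, n_sites)
    ids: np.ndarray  # variant id strings
    allele_a: np.ndarray
    allele_b: np.ndarray
    chrom: str = "20"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (n_hap, n_sites)")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype column count must match number of positions")
        if self.positions.size > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele B (coded 1) per site."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_sites(self, index: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            positions=self.positions[index],
            haplotypes=self.haplotypes[:, index],
            ids=self.ids[index],
            allele_a=self.allele_a[index],
            allele_b=self.allele_b[index],
            chrom=self.chrom,
        )

    def variant_records(self, source: str = "imputed_only") -> list[VariantRecord]:
        return [
            VariantRecord(
                id=str(self.ids[i]),
                chrom=self.chrom,
                pos=int(self.positions[i]),
                allele_a=str(self.allele_a[i]),
                allele_b=str(self.allele_b[i]),
                source=source,
            )
            for i in range(self.n_sites)
        ]


@dataclass
class GenotypeMatrix:
    """Hard genotypes {0, 1, 2, MISSING} at typed sites.

    ``genotypes`` has shape (n_variants, n_samples); values count copies
    of allele B.  Missing calls carry :data:`MISSING`.
    """

    positions: np.ndarray
    ids: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    genotypes: np.ndarray  # int8 (n_var, n_samp)
    samples: list[str]
    chrom: str = "20"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotypes shape must be (n_variants, n_samples)")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def subset(self, variant_index: np.ndarray | None = None,
               sample_index: np.ndarray | None = None) -> "GenotypeMatrix":
        vi = np.arange(self.n_variants) if variant_index is None else np.asarray(variant_index)
        si = np.arange(self.n_samples) if sample_index is None else np.asarray(sample_index)
        return GenotypeMatrix(
            positions=self.positions[vi],
            ids=self.ids[vi],
            allele_a=self.allele_a[vi],
            allele_b=self.allele_b[vi],
            genotypes=self.genotypes[np.ix_(vi, si)],
            samples=[self.samples[i] for i in si],
            chrom=self.chrom,
        )


@dataclass
class GenotypeProbabilities:
    """Per-variant, per-sample genotype posterior triplets.

    ``probs`` has shape (n_variants, n_samples, 3) holding
    (p0, p1, p2) = P(AA), P(AB), P(BB).  ``missing`` flags cells whose
    input carried no information (all-zero GEN triplet); their stored
    triplet is uniform.  Missingness is an explicit mask, never NaN.
    """

    variants: list[VariantRecord]
    samples: list[str]
    probs: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        n_var, n_samp = len(self.variants), len(self.samples)
        if self.probs.shape != (n_var, n_samp, 3):
            raise ValueError(
                f"probs shape {self.probs.shape} != ({n_var}, {n_samp}, 3)")
        if self.missing is None:
            self.missing = np.zeros((n_var, n_samp), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        s = self.probs.sum(axis=2)
        if n_var and n_samp and not np.allclose(s, 1.0, atol=1e-6):
            raise ValueError("genotype probability triplets must sum to 1 within 1e-6")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE

def _parse_gen_line(line: str, lineno: int, n_samples: int | None):
    parts = line.split()
    if n_samples is not None and len(parts) != 5 + 3 * n_samples:
        raise FormatError(
            f"line {lineno}: expected {5 + 3 * n_samples} columns, got {len(parts)}")
    if (len(parts) - 5) % 3 != 0 or len(parts) < 8:
        raise FormatError(f"line {lineno}: column count {len(parts)} is not 5 + 3*N")
    try:
        trip = np.array(parts[5:], dtype=np.float64).reshape(-1, 3)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric genotype probability") from exc
    return parts[:5], trip


def read_gen(path: str | Path, sample_path: str | Path,
             chrom: str = "20") -> GenotypeProbabilities:
    """Read an Oxford GEN + SAMPLE pair into genotype probabilities.

    GEN columns are ``snp_id rsid pos alleleA alleleB`` followed by one
    (p0, p1, p2) triplet per sample.  All-zero triplets mark a missing
    call (SNPTEST convention); they are flagged in the missing mask and
    stored as the uninformative uniform triplet.  Other triplets are
    renormalized to sum to 1.
    """
    samples = _read_sample_file(sample_path)
    variants: list[VariantRecord] = []
    trips: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            meta, trip = _parse_gen_line(line, lineno, len(samples))
            snp_id, rsid, pos, a0, a1 = meta
            variants.append(VariantRecord(
                id=snp_id, chrom=chrom, pos=int(pos), allele_a=a0, allele_b=a1))
            trips.append(trip)
    if not variants:
        probs = np.zeros((0, len(samples), 3))
        return GenotypeProbabilities(variants, samples, probs)
    probs = np.stack(trips)
    sums = probs.sum(axis=2)
    missing = sums <= 0.0
    safe = np.where(missing, 1.0, sums)
    probs = probs / safe[:, :, None]
    probs[missing] = 1.0 / 3.0
    return GenotypeProbabilities(variants, samples, probs, missing)


def _read_sample_file(path: str | Path) -> list[str]:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: SAMPLE file needs header + type line")
    return [ln[1] for ln in lines[2:]]  # ID_2 column


def write_gen(gp: GenotypeProbabilities, path: str | Path,
              sample_path: str | Path) -> None:
    """Write GEN + SAMPLE with 6-decimal fixed-precision probabilities."""
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in gp.samples:
            fh.write(f"{s} {s} 0\n")
    with open(path, "w") as fh:
        for i, v in enumerate(gp.variants):
            row = gp.probs[i].copy()
            row[gp.missing[i]] = 0.0  # missing call -> all-zero triplet
            trip_txt = " ".join(f"{p:.6f}" for p in row.ravel())
            fh.write(f"{v.id} {v.id} {v.pos} {v.allele_a} {v.allele_b} {trip_txt}\n")


def genotypes_to_gen(gm: GenotypeMatrix) -> GenotypeProbabilities:
    """Lift hard genotype calls to certain (one-hot) probability triplets."""
    n_var, n_samp = gm.genotypes.shape
    probs = np.zeros((n_var, n_samp, 3))
    missing = gm.genotypes == MISSING
    g = np.clip(gm.genotypes, 0, 2)
    idx_v, idx_s = np.meshgrid(np.arange(n_var), np.arange(n_samp), indexing="ij")
    probs[idx_v, idx_s, g] = 1.0
    probs[missing] = 1.0 / 3.0
    variants = [
        VariantRecord(id=str(gm.ids[i]), chrom=gm.chrom, pos=int(gm.positions[i]),
                      allele_a=str(gm.allele_a[i]), allele_b=str(gm.allele_b[i]),
                      source="typed")
        for i in range(n_var)
    ]
    return GenotypeProbabilities(variants, list(gm.samples), probs, missing)


# ---------------------------------------------------------------------------
# IMPUTE-style .hap / .legend

def write_hap_legend(panel: HaplotypePanel, hap_path: str | Path,
                     legend_path: str | Path) -> None:
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1\n")
        for i in range(panel.n_sites):
            fh.write(f"{panel.ids[i]} {panel.positions[i]} "
                     f"{panel.allele_a[i]} {panel.allele_b[i]}\n")
    np.savetxt(hap_path, panel.haplotypes.T, fmt="%d", delimiter=" ")


def read_hap_legend(hap_path: str | Path, legend_path: str | Path,
                    chrom: str = "20") -> HaplotypePanel:
    with open(legend_path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise FormatError(f"{legend_path}: missing legend header")
        rows = [ln.split() for ln in fh if ln.strip()]
    haps = np.loadtxt(hap_path, dtype=np.uint8, ndmin=2).T
    if haps.shape[1] != len(rows):
        raise FormatError("hap/legend row-count mismatch")
    return HaplotypePanel(
        positions=np.array([int(r[1]) for r in rows], dtype=np.int64),
        haplotypes=haps,
        ids=np.array([r[0] for r in rows]),
        allele_a=np.array([r[2] for r in rows]),
        allele_b=np.array([r[3] for r in rows]),
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# VCF

def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a phased-GT VCF 4.2 for a haplotype panel (pairs = samples)."""
    if panel.n_haplotypes % 2:
        raise ValueError("panel must contain an even number of haplotypes")
    n_ind = panel.n_haplotypes // 2
    sample_names = [f"ind{i:04d}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        h = panel.haplotypes
        for i in range(panel.n_sites):
            gts = "\t".join(f"{h[2 * j, i]}|{h[2 * j + 1, i]}" for j in range(n_ind))
            fh.write(f"{panel.chrom}\t{panel.positions[i]}\t{panel.ids[i]}\t"
                     f"{panel.allele_a[i]}\t{panel.allele_b[i]}\t.\t.\tGT\t{gts}\n")


def _ds_to_triplet(d: float) -> tuple[float, float, float]:
    # Hardy-Weinberg-free expansion of a dosage into a triplet
    p2 = max(0.0, d - 1.0)
    p1 = d - 2.0 * p2
    p0 = 1.0 - p1 - p2
    return (p0, p1, p2)


def read_vcf_gp(path: str | Path) -> GenotypeProbabilities:
    """Read VCF records carrying GP (preferred) or DS into triplets.

    DS-only records are expanded with p2 = max(0, d-1), p1 = d - 2*p2,
    p0 = 1 - p1 - p2 and logged as approximate.  Records with neither
    field raise :class:`FormatError`.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("read_vcf_gp requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    trips: list[np.ndarray] = []
    any_ds = False
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        variants.append(VariantRecord(
            id=rec.ID or f"{rec.CHROM}_{rec.POS}", chrom=str(rec.CHROM),
            pos=rec.POS, allele_a=rec.REF, allele_b=alt))
        gp = rec.format("GP")
        if gp is not None:
            trips.append(np.asarray(gp, dtype=np.float64))
            continue
        ds = rec.format("DS")
        if ds is None:
            raise FormatError(
                f"{rec.CHROM}:{rec.POS}: record has neither GP nor DS")
        any_ds = True
        trips.append(np.array([_ds_to_triplet(float(d)) for d in ds.ravel()]))
    if any_ds:
        logger.warning("DS-only records expanded to triplets (approximate)")
    if not variants:
        return GenotypeProbabilities([], samples, np.zeros((0, len(samples), 3)))
    probs = np.stack(trips)
    sums = probs.sum(axis=2)
    missing = ~np.isfinite(sums) | (sums <= 0)
    probs[missing] = 1.0 / 3.0
    sums = probs.sum(axis=2)
    probs = probs / sums[:, :, None]
    return GenotypeProbabilities(variants, samples, probs, missing)


# ---------------------------------------------------------------------------
# MAF tables (dbSNP-like TSV: id, chrom, pos, minor_allele, maf)

def read_maf_table(path: str | Path) -> dict[str, tuple[str, float]]:
    """Read a TSV MAF table into id -> (minor_allele, maf).

    A maf of exactly 0 is a legal "null-frequency" record.  Values
    outside [0, 0.5] reject the record with a warning; duplicate ids
    keep the last occurrence with a warning.
    """
    table: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for name in ("id", "minor_allele", "maf"):
            if name not in cols:
                raise FormatError(f"{path}: missing column {name!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            vid = parts[cols["id"]]
            try:
                maf = float(parts[cols["maf"]])
            except ValueError:
                warnings.warn(f"{path} line {lineno}: non-numeric maf, skipped")
                continue
            if not (0.0 <= maf <= 0.5):
                warnings.warn(
                    f"{path} line {lineno}: maf {maf} outside [0, 0.5], skipped")
                continue
            if vid in table:
                warnings.warn(f"{path} line {lineno}: duplicate id {vid}, last wins")
            table[vid] = (parts[cols["minor_allele"]], maf)
    return table


def write_maf_table(entries: Iterable[tuple[str, str, int, str, float]],
                    path: str | Path) -> None:
    """Write rows of (id, chrom, pos, minor_allele, maf) as TSV."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\tminor_allele\tmaf\n")
        for vid, chrom, pos, allele, maf in entries:
            fh.write(f"{vid}\t{chrom}\t{pos}\t{allele}\t{maf:.6g}\n")
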