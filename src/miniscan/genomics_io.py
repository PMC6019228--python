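"""Readers, writers and shared coordinate conventions.

All coordinates inside the package are 1-based and inclusive, matching how
genomic positions are reported in the variant-calling literature (a SNV "at
105,258,161 bp" is position 105258161).  The only place 0-based half-open
coordinates appear is at the BED file boundary, where :func:`write_bed` /
:func:`read_bed` convert.

Genotypes are coded ``0`` (homozygous reference), ``1`` (heterozygous),
``2`` (homozygous alternate) and ``-1`` (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GENOTYPE_CODES = (-1, 0, 1, 2)
EFFECT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: chromosome labels excluded from autosomal scans by default
DEFAULT_EXCLUDED_CHROMS = ("X", "chrX", "ChrX")
DEFAULT_EXCLUDED_PREFIXES = ("ChrUn", "chrUn", "Un")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chromosome}"
            )
        if self.start < 1:
            raise ValueError(f"interval start {self.start} < 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end


@dataclass(frozen=True)
class VariantSite:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    qual: float = float("nan")
    depth_per_sample: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position {self.position} < 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref allele equals alt allele")

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.alt_allele)


@dataclass(frozen=True)
class AnnotationRecord:
    chromosome: str
    position: int
    alt_allele: str
    effect_class: str
    deleterious_score: Optional[float] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"effect_class {self.effect_class!r} not in {EFFECT_CLASSES}"
            )
        if self.deleterious_score is not None and not (
            0.0 <= self.deleterious_score <= 1.0
        ):
            raise ValueError(f"deleterious score {self.deleterious_score} not in [0,1]")

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.alt_allele)


@dataclass
class TraitRecord:
    """One phenotyped individual: withers height, optional cannon bone
    circumference, and genotype codes at the candidate loci."""

    sample_id: str
    height_cm: Optional[float]
    cannon_cm: Optional[float] = None
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height_cm is not None and self.height_cm <= 0:
            raise ValueError(f"height {self.height_cm} must be positive")


class GenotypeMatrix:
    """Samples x variants diploid genotype calls.

    Parameters
    ----------
    sample_ids : sequence of str
    variants : sequence of VariantSite, sorted by (chromosome, position)
    calls : (n_samples, n_variants) integer array with codes in {-1,0,1,2}
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantSite],
        calls: np.ndarray,
    ):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sample_ids), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(sample_ids)}, {len(variants)})"
            )
        bad = ~np.isin(calls, GENOTYPE_CODES)
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(calls[bad])}")
        last: dict = {}
        for v in variants:
            if v.chromosome in last and v.position <= last[v.chromosome]:
                raise ValueError(
                    f"variants not strictly increasing on {v.chromosome} "
                    f"at position {v.position}"
                )
            last[v.chromosome] = v.position
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        if len(self._sample_index) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> list:
        seen: list = []
        for v in self.variants:
            if not seen or seen[-1] != v.chromosome:
                seen.append(v.chromosome)
        return seen

    def sample_row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_index_checked(s) for s in sample_ids], dtype=int)

    def _sample_index_checked(self, sample_id: str) -> int:
        if sample_id not in self._sample_index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self._sample_index[sample_id]

    def positions(self, chromosome: str) -> np.ndarray:
        return np.array(
            [v.position for v in self.variants if v.chromosome == chromosome],
            dtype=np.int64,
        )

    def chrom_mask(self, chromosome: str) -> np.ndarray:
        return np.array([v.chromosome == chromosome for v in self.variants])


def _is_excluded_chrom(name: str, include_x_un: bool) -> bool:
    if include_x_un:
        return False
    if name in DEFAULT_EXCLUDED_CHROMS:
        return True
    return any(name.startswith(p) for p in DEFAULT_EXCLUDED_PREFIXES)


def read_vcf(
    path,
    sample_subset: Optional[Sequence[str]] = None,
    min_depth: int = 3,
    max_depth: int = 60,
    min_qual: float = 20.0,
    include_x_and_unplaced: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Per-sample genotypes at sites where FORMAT/DP falls outside
    ``[min_depth, max_depth]`` are set to missing; sites with QUAL below
    ``min_qual`` are dropped, as are sites where every retained sample is
    missing.  Indels and multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    if min_depth > max_depth:
        raise ValueError(f"min_depth {min_depth} > max_depth {max_depth}")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exception on parse failure
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    all_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in all_samples]
        if missing:
            raise KeyError(f"unknown sample ids in VCF: {missing}")
        keep = [all_samples.index(s) for s in sample_subset]
        sample_ids = list(sample_subset)
    else:
        keep = list(range(len(all_samples)))
        sample_ids = all_samples

    variants: list = []
    rows: list = []
    for rec in vcf:
        if _is_excluded_chrom(rec.CHROM, include_x_and_unplaced):
            continue
        if len(rec.ALT) != 1:
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # SNVs only
        qual = rec.QUAL if rec.QUAL is not None else float("nan")
        if not np.isnan(qual) and qual < min_qual:
            continue
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
        codes = np.asarray(rec.gt_types, dtype=np.int16)[keep]
        codes = np.where(codes == 3, -1, codes).astype(np.int8)
        depth = rec.format("DP")
        depths = None
        if depth is not None:
            depths = np.asarray(depth, dtype=float).reshape(-1)[keep]
            bad_dp = np.isnan(depths) | (depths < min_depth) | (depths > max_depth)
            codes = np.where(bad_dp, -1, codes).astype(np.int8)
        if (codes == -1).all():
            continue
        variants.append(
            VariantSite(
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                qual=qual,
                depth_per_sample=tuple(int(d) for d in depths)
                if depths is not None and not np.isnan(depths).any()
                else None,
            )
        )
        rows.append(codes)
    vcf.close()

    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    order = sorted(
        range(len(variants)), key=lambda i: (variants[i].chromosome, variants[i].position)
    )
    variants = [variants[i] for i in order]
    if calls.shape[1]:
        calls = calls[:, order]
    return GenotypeMatrix(sample_ids, variants, calls)


def write_bed(intervals: Sequence[GenomicInterval], path, payloads=None) -> None:
    """Write intervals as BED3(+payload columns), converting to 0-based
    half-open coordinates."""
    intervals = list(intervals)
    if payloads is not None and len(payloads) != len(intervals):
        raise ValueError("payloads length mismatch")
    try:
        order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chromosome, intervals[i].start))
    except TypeError as exc:
        raise ValueError(f"unsortable chromosomes: {exc}") from exc
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            fields = [iv.chromosome, str(iv.start - 1), str(iv.end)]
            if payloads is not None:
                fields.extend(str(x) for x in payloads[i])
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list:
    """Read a BED3+ file back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start0, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start0) + 1, int(end)))
    return out


_GT_SEPARATORS = ("/", "|")


def _genotype_string_to_code(gt: str, mutant_allele: Optional[str]) -> int:
    gt = gt.strip()
    if gt in ("", "NA", "nan", "./.", ".|.", "."):
        return -1
    if gt in ("0", "1", "2", "-1"):
        return int(gt)
    for sep in _GT_SEPARATORS:
        if sep in gt:
            a, b = gt.split(sep, 1)
            if mutant_allele is None:
                raise ValueError(
                    f"genotype string {gt!r} needs a declared mutant allele"
                )
            return int(a == mutant_allele) + int(b == mutant_allele)
    raise ValueError(f"cannot parse genotype {gt!r}")


def read_phenotypes(
    path, mutant_alleles: Optional[Mapping[str, str]] = None
) -> list:
    """Read the phenotype TSV: sample_id, height_cm, optional cannon_cm,
    then one column per candidate locus.

    Genotypes may be numeric codes or allele strings like ``A/A``; allele
    strings require ``mutant_alleles`` mapping each locus column to the
    size-associated (counted) allele.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "height_cm" not in df.columns:
        raise ValueError("phenotype table needs sample_id and height_cm columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids: {dup}")
    locus_cols = [c for c in df.columns if c not in ("sample_id", "height_cm", "cannon_cm")]
    records = []
    for _, row in df.iterrows():
        height = row["height_cm"]
        height_v = None if pd.isna(height) or height in ("NA", "") else float(height)
        cannon_v = None
        if "cannon_cm" in df.columns:
            cannon = row["cannon_cm"]
            if not (pd.isna(cannon) or cannon in ("NA", "")):
                cannon_v = float(cannon)
        genos = {}
        for col in locus_cols:
            mut = mutant_alleles.get(col) if mutant_alleles else None
            raw = row[col]
            genos[col] = -1 if pd.isna(raw) else _genotype_string_to_code(str(raw), mut)
        records.append(
            TraitRecord(
                sample_id=row["sample_id"],
                height_cm=height_v,
                cannon_cm=cannon_v,
                genotypes=genos,
            )
        )
    return records


def write_phenotypes(records: Sequence[TraitRecord], path, loci: Optional[Sequence[str]] = None) -> None:
    if loci is None:
        loci = sorted({k for r in records for k in r.genotypes})
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "height_cm", "cannon_cm", *loci]) + "\n")
        for r in records:
            row = [
                r.sample_id,
                "NA" if r.height_cm is None else f"{r.height_cm:.4f}",
                "NA" if r.cannon_cm is None else f"{r.cannon_cm:.4f}",
            ]
            row += [str(r.genotypes.get(l, -1)) for l in loci]
            fh.write("\t".join(row) + "\n")


def read_annotations(path) -> list:
    """Read the annotation TSV (chrom, pos, alt, effect_class, sift_score, gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str, "gene": str})
    out = []
    for _, row in df.iterrows():
        score = row.get("sift_score")
        out.append(
            AnnotationRecord(
                chromosome=str(row["chrom"]),
                position=int(row["pos"]),
                alt_allele=str(row["alt"]),
                effect_class=str(row["effect_class"]),
                deleterious_score=None if pd.isna(score) else float(score),
                gene=None if pd.isna(row.get("gene")) else str(row["gene"]),
            )
        )
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list:
    """Merge overlapping or book-ended (adjacent) intervals per chromosome."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e + 1:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_two(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> list:
    """Base-pair intersection of two interval sets (each set merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    by_chrom_b: dict = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chromosome, []).append(iv)
    for iv in a:
        for jv in by_chrom_b.get(iv.chromosome, []):
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if lo <= hi:
                out.append(GenomicInterval(iv.chromosome, lo, hi))
    return sorted(out, key=lambda x: (x.chromosome, x.start))
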