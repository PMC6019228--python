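"""Runs of homozygosity: calling, sharing, coverage and dating.

The caller reproduces the two-pass sliding-window strategy popularised by
PLINK's ``--homozyg`` scan: windows of consecutive SNPs are scored as
homozygous when they tolerate at most a few heterozygous and missing calls,
each SNP is flagged by the fraction of overlapping homozygous windows, and
maximal runs of flagged SNPs become segments after gap-splitting and
run-level filters (minimum SNP count, minimum length, maximum mean SNP
spacing).

Dating converts a homozygous tract's physical length into an expected age:
a haplotype of recombination length c Morgans survives unbroken for about
1/(2c) generations, so with a uniform 1 cM/Mb map an L-Mb tract dates to
50/L generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .genomics_io import GenomicInterval, GenotypeMatrix, merge_intervals


@dataclass
class RohParams:
    """Sliding-window homozygosity-scan parameters.

    Defaults: 50-SNP windows tolerating 3 heterozygous and 10 missing
    calls, segments of >= 50 SNPs spanning >= 150 kb with mean spacing
    <= 3 kb/SNP, split at inter-SNP gaps > 100 kb.  ``window_hit_threshold``
    is the minimum fraction of overlapping homozygous windows for a SNP to
    be flagged (0.05, the conventional default).
    """

    window_snps: int = 50
    min_snps: int = 50
    min_length_bp: int = 150_000
    max_missing_per_window: int = 10
    max_het_per_window: int = 3
    max_gap_bp: int = 100_000
    max_kb_per_snp: float = 3.0
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("window_snps", "min_snps", "min_length_bp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.window_hit_threshold <= 1):
            raise ValueError("window_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    interval: GenomicInterval
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.interval.length_bp


@dataclass
class SharedRegion:
    """An interval homozygous in every required sample, with the per-sample
    segments supporting it."""

    interval: GenomicInterval
    supporting: Dict[str, List[RohSegment]] = field(default_factory=dict)


@dataclass(frozen=True)
class AgeEstimate:
    """Expected age of a homozygous tract under the 1/(2c) rule."""

    length_mb: float
    c_morgans: float
    generations: float
    years: float
    cm_per_mb: float = 1.0
    generation_interval_years: float = 10.0

    @property
    def generations_2dp(self) -> float:
        return round(self.generations, 2)

    @property
    def years_2dp(self) -> float:
        return round(self.years, 2)


def _flag_snps(het: np.ndarray, missing: np.ndarray, params: RohParams) -> np.ndarray:
    """Pass 1: fraction of overlapping homozygous windows per SNP."""
    n = len(het)
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(missing)])
    # window i covers SNPs [i, i+w)
    n_win = n - w + 1
    win_het = het_c[w:] - het_c[:-w]
    win_mis = mis_c[w:] - mis_c[:-w]
    win_ok = (win_het <= params.max_het_per_window) & (
        win_mis <= params.max_missing_per_window
    )
    ok_c = np.concatenate([[0], np.cumsum(win_ok)])
    idx = np.arange(n)
    first = np.maximum(0, idx - w + 1)
    last = np.minimum(n_win - 1, idx)
    n_overlap = last - first + 1
    n_ok = ok_c[last + 1] - ok_c[first]
    return (n_ok / n_overlap) >= params.window_hit_threshold


def _runs_passing(
    flagged: np.ndarray,
    positions: np.ndarray,
    params: RohParams,
) -> List[tuple]:
    """Pass 2: maximal flagged runs, gap-split, run-level filters.

    Returns (start_idx, end_idx) index pairs (inclusive).
    """
    out = []
    n = len(flagged)
    i = 0
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1]:
            j += 1
        # split run [i, j] at gaps > max_gap_bp
        s = i
        for k in range(i, j):
            if positions[k + 1] - positions[k] > params.max_gap_bp:
                out.append((s, k))
                s = k + 1
        out.append((s, j))
        i = j + 1
    kept = []
    for s, e in out:
        n_snps = e - s + 1
        length_bp = int(positions[e] - positions[s] + 1)
        if n_snps < params.min_snps:
            continue
        if length_bp < params.min_length_bp:
            continue
        if (length_bp / 1000.0) / n_snps > params.max_kb_per_snp:
            continue
        kept.append((s, e))
    return kept


def call_roh(
    genotypes: GenotypeMatrix, sample_id: str, params: RohParams | None = None
) -> List[RohSegment]:
    """Call ROH segments for one sample, per chromosome.

    Chromosomes with fewer SNPs than one window yield no calls.  Segment
    boundaries are the first and last SNP positions of the retained run.
    """
    if params is None:
        params = RohParams()
    row = genotypes.sample_row(sample_id)
    segments: List[RohSegment] = []
    for chrom in genotypes.chromosomes:
        mask = genotypes.chrom_mask(chrom)
        codes = row[mask]
        positions = genotypes.positions(chrom)
        if np.any(np.diff(positions) <= 0):
            raise ValueError(f"unsorted positions on chromosome {chrom}")
        het = (codes == 1).astype(np.int64)
        missing = (codes == -1).astype(np.int64)
        flagged = _flag_snps(het, missing, params)
        for s, e in _runs_passing(flagged, positions, params):
            segments.append(
                RohSegment(
                    sample_id=sample_id,
                    interval=GenomicInterval(chrom, int(positions[s]), int(positions[e])),
                    n_snps=e - s + 1,
                )
            )
    return segments


def shared_regions(
    segments_by_sample: Dict[str, Sequence[RohSegment]],
    required_samples: Sequence[str],
) -> List[SharedRegion]:
    """Base-pair intersection of ROH coverage across all required samples.

    Returns maximal intervals covered by at least one segment of *every*
    required sample; empty when any sample lacks coverage.
    """
    for s in required_samples:
        if s not in segments_by_sample:
            raise KeyError(f"unknown sample {s!r}")
    if not required_samples:
        return []
    coverage = None
    for s in required_samples:
        ivs = merge_intervals([seg.interval for seg in segments_by_sample[s]])
        if coverage is None:
            coverage = ivs
        else:
            coverage = _intersect_merged(coverage, ivs)
        if not coverage:
            return []
    out = []
    for iv in coverage:
        supporting = {
            s: [seg for seg in segments_by_sample[s] if seg.interval.overlaps(iv)]
            for s in required_samples
        }
        out.append(SharedRegion(interval=iv, supporting=supporting))
    return out


def _intersect_merged(a: List[GenomicInterval], b: List[GenomicInterval]) -> List[GenomicInterval]:
    out = []
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    for iv in a:
        for jv in by_chrom.get(iv.chromosome, []):
            lo, hi = max(iv.start, jv.start), min(iv.end, jv.end)
            if lo <= hi:
                out.append(GenomicInterval(iv.chromosome, lo, hi))
    return sorted(out, key=lambda x: (x.chromosome, x.start))


def genome_fraction(
    regions: Sequence[GenomicInterval], chromosome_lengths: Dict[str, int]
) -> float:
    """Fraction of the genome covered by the (merged) regions."""
    merged = merge_intervals(regions)
    total = 0
    for iv in merged:
        if iv.chromosome not in chromosome_lengths:
            raise KeyError(f"unknown chromosome {iv.chromosome!r}")
        if iv.end > chromosome_lengths[iv.chromosome]:
            raise ValueError(
                f"region {iv} exceeds chromosome length "
                f"{chromosome_lengths[iv.chromosome]}"
            )
        total += iv.length_bp
    genome = sum(chromosome_lengths.values())
    return total / genome if genome else 0.0


def date_roh(
    length_mb: float,
    cm_per_mb: float = 1.0,
    generation_interval_years: float = 10.0,
) -> AgeEstimate:
    """Date a homozygous tract: c = Mb * cM/Mb / 100 Morgans, age = 1/(2c)
    generations, years = generations * generation interval.

    Full precision is retained; round to 2 decimals for reporting via
    ``generations_2dp`` / ``years_2dp``.
    """
    if length_mb <= 0:
        raise ValueError("length_mb must be > 0")
    c = length_mb * cm_per_mb / 100.0
    generations = 1.0 / (2.0 * c)
    years = generations * generation_interval_years
    return AgeEstimate(
        length_mb=length_mb,
        c_morgans=c,
        generations=generations,
        years=years,
        cm_per_mb=cm_per_mb,
        generation_interval_years=generation_interval_years,
    )
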