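"""Windowed Fst between a small case group and a pooled control panel.

Uses the Hudson estimator with the finite-sample correction, windowed as a
ratio of averages: per SNP the numerator is the squared allele-frequency
difference minus the sampling terms, the denominator is the between-
population heterozygosity, and a window's Fst is sum(N) / sum(D) over its
SNPs.  The ratio-of-averages form is the standard choice for unequal and
very small sample sizes (e.g. 3 cases vs 24 controls), where averaging
per-SNP ratios is badly behaved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomics_io import GenomicInterval, GenotypeMatrix
from .roh_scan import SharedRegion


@dataclass(frozen=True)
class FstWindow:
    interval: GenomicInterval
    fst: float
    n_snps: int


def hudson_components(
    case_calls: np.ndarray, control_calls: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Hudson numerator/denominator with finite-sample correction.

    ``case_calls`` / ``control_calls`` are (n_samples, n_snps) genotype-code
    arrays.  Allele counts use non-missing genotypes only.  SNPs where
    either group has fewer than 2 observed allele copies are masked out.

    Returns (N_hat, D_hat, informative_mask).
    """
    def freqs(calls):
        obs = calls >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return p, n_alleles

    p1, n1 = freqs(np.asarray(case_calls))
    p2, n2 = freqs(np.asarray(control_calls))
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    # monomorphic in both groups: D = 0, no information
    ok = ok & (den > 0)
    return num, den, ok


def windowed_fst(
    genotypes: GenotypeMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    window_bp: int = 50_000,
    step_bp: int = 10_000,
    chromosome_lengths: Optional[Dict[str, int]] = None,
) -> List[FstWindow]:
    """Sliding-window Hudson Fst, windows tiled per chromosome from
    position 1.  Windows with no informative SNP get fst = NaN.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise ValueError("case and control groups must each be non-empty")
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control sets must be disjoint")
    ci = genotypes.sample_indices(case_ids)
    ki = genotypes.sample_indices(control_ids)

    windows: List[FstWindow] = []
    for chrom in genotypes.chromosomes:
        mask = genotypes.chrom_mask(chrom)
        pos = genotypes.positions(chrom)
        num, den, ok = hudson_components(
            genotypes.calls[np.ix_(ci, np.flatnonzero(mask))],
            genotypes.calls[np.ix_(ki, np.flatnonzero(mask))],
        )
        # prefix sums over informative SNPs -> O(1) per window
        num_c = np.concatenate([[0.0], np.cumsum(np.where(ok, num, 0.0))])
        den_c = np.concatenate([[0.0], np.cumsum(np.where(ok, den, 0.0))])
        cnt_c = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        chrom_end = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else int(pos.max())
        )
        starts = np.arange(1, chrom_end + 1, step_bp, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp - 1, side="right")
        for s, l, h in zip(starts, lo, hi):
            n_snps = int(cnt_c[h] - cnt_c[l])
            d = float(den_c[h] - den_c[l])
            if n_snps and d > 0:
                fst = float((num_c[h] - num_c[l]) / d)
            else:
                fst = float("nan")
            windows.append(
                FstWindow(
                    GenomicInterval(chrom, int(s), int(s) + window_bp - 1),
                    fst,
                    n_snps,
                )
            )
    return windows


def top_percentile(
    windows: Sequence[FstWindow], q: float = 0.99
) -> Tuple[float, List[FstWindow]]:
    """Empirical q-quantile threshold (linear interpolation) over non-NaN
    window values; returns (threshold, windows with fst >= threshold)."""
    values = np.array([w.fst for w in windows], dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        raise ValueError("no windows with informative SNPs")
    threshold = float(np.quantile(finite, q))
    selected = [w for w in windows if not np.isnan(w.fst) and w.fst >= threshold]
    return threshold, selected


def overlap_with_roh(
    selected_windows: Sequence[FstWindow],
    regions: Sequence[SharedRegion],
) -> List[Tuple[SharedRegion, List[FstWindow], float]]:
    """For each shared-ROH region, the selected Fst windows sharing >= 1 bp
    with it and their maximum Fst.  Regions with no overlap are omitted."""
    out = []
    for region in regions:
        hits = [w for w in selected_windows if w.interval.overlaps(region.interval)]
        if hits:
            out.append((region, hits, max(w.fst for w in hits)))
    return out


def merge_selected_windows(selected: Sequence[FstWindow]) -> List[GenomicInterval]:
    """Optional merge of overlapping selected windows into regions (the
    alternative reading of 'regions' for percentile reporting)."""
    from .genomics_io import merge_intervals

    return merge_intervals([w.interval for w in selected])
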