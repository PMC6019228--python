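"""Candidate-variant screening inside shared homozygosity regions.

Two parallel filter routes operate on variants that fall inside shared ROH
regions: a functional route keeping variants with predicted HIGH/MODERATE
effects (deleteriousness scores carried as metadata), and an exclusivity
route keeping variants homozygous for the alternate allele in every case
sample and homozygous reference in every control.  Samples with unclear
phenotype can be excluded from both groups before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .genomics_io import (
    AnnotationRecord,
    GenomicInterval,
    GenotypeMatrix,
    VariantSite,
    merge_intervals,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    variant: VariantSite
    in_region: GenomicInterval
    effect_class: Optional[str] = None
    deleterious: Optional[bool] = None
    exclusive: bool = False


def variants_in_regions(
    genotypes: GenotypeMatrix, regions: Sequence[GenomicInterval]
) -> List[VariantSite]:
    """Variants whose position lies inside any region (1-based inclusive;
    boundary positions count)."""
    merged = merge_intervals(regions)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    out = []
    for v in genotypes.variants:
        for iv in by_chrom.get(v.chromosome, []):
            if iv.start <= v.position <= iv.end:
                out.append(v)
                break
    return out


def effect_filter(
    variants: Sequence[VariantSite],
    annotations: Sequence[AnnotationRecord],
    classes: Set[str] = frozenset({"HIGH", "MODERATE"}),
) -> List[VariantSite]:
    """Keep variants annotated with an effect class in ``classes``.

    Join key is (chromosome, position, alt allele).  Unannotated variants
    are dropped (count logged); duplicate annotations for one key error.
    """
    table: Dict[tuple, AnnotationRecord] = {}
    for ann in annotations:
        if ann.key in table:
            raise ValueError(f"duplicate annotation for {ann.key}")
        table[ann.key] = ann
    kept, unannotated = [], 0
    for v in variants:
        ann = table.get(v.key)
        if ann is None:
            unannotated += 1
            continue
        if ann.effect_class in classes:
            kept.append(v)
    if unannotated:
        logger.info("effect_filter: dropped %d unannotated variants", unannotated)
    return kept


def exclusivity_filter(
    genotypes: GenotypeMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    variants: Optional[Sequence[VariantSite]] = None,
    excluded_ids: Sequence[str] = (),
) -> List[VariantSite]:
    """Variants homozygous-alternate in every case and homozygous-reference
    in every control.

    A missing call in any required sample disqualifies the variant (strict
    reading: false positives are costlier than false negatives in a
    candidate screen).  ``excluded_ids`` (e.g. samples of unclear
    phenotype) are removed from both groups before testing.
    """
    excluded = set(excluded_ids)
    cases = [s for s in case_ids if s not in excluded]
    controls = [s for s in control_ids if s not in excluded]
    if not cases:
        raise ValueError("case set is empty after exclusions")
    if set(cases) & set(controls):
        raise ValueError("case and control sets must be disjoint")
    ci = genotypes.sample_indices(cases)
    ki = genotypes.sample_indices(controls)
    if variants is None:
        variants = genotypes.variants
    index = {v.key: j for j, v in enumerate(genotypes.variants)}
    out = []
    for v in variants:
        j = index.get(v.key)
        if j is None:
            continue
        col = genotypes.calls[:, j]
        if np.all(col[ci] == 2) and np.all(col[ki] == 0):
            out.append(v)
    return out


def screen(
    genotypes: GenotypeMatrix,
    regions: Sequence[GenomicInterval],
    annotations: Sequence[AnnotationRecord],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    classes: Set[str] = frozenset({"HIGH", "MODERATE"}),
    excluded_ids: Sequence[str] = (),
    deleterious_cutoff: float = 0.05,
) -> List[ScreenResult]:
    """Full screen: region membership, effect class, and exclusivity.

    Returns one :class:`ScreenResult` per variant surviving the region +
    effect filters, with its exclusivity flag and (metadata-only)
    deleteriousness at the conventional score cutoff.
    """
    merged = merge_intervals(regions)
    in_regions = variants_in_regions(genotypes, merged)
    effected = effect_filter(in_regions, annotations, classes)
    exclusive = {
        v.key
        for v in exclusivity_filter(
            genotypes, case_ids, control_ids, effected, excluded_ids
        )
    }
    ann_table = {a.key: a for a in annotations}
    results = []
    for v in effected:
        region = next(iv for iv in merged if iv.contains(v.chromosome, v.position))
        ann = ann_table[v.key]
        deleterious = (
            None
            if ann.deleterious_score is None
            else bool(ann.deleterious_score < deleterious_cutoff)
        )
        results.append(
            ScreenResult(
                variant=v,
                in_region=region,
                effect_class=ann.effect_class,
                deleterious=deleterious,
                exclusive=v.key in exclusive,
            )
        )
    return results
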