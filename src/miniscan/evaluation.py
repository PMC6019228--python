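"""Seeded end-to-end recovery experiments.

Each function runs one stage of the pipeline on synthetic data generated
under the study conditions the pipeline targets and measures how well the
planted truth is recovered.  They are used both by the test suite and by
the reproduction script, so the experimental designs live here, once.

Design notes
------------
* ROH recovery plants one autozygous tract per replicate with length drawn
  uniformly from 0.28-3.34 Mb, the size range of candidate-region ROHs in
  small-pony selection scans, at ~1 SNP/kb marker density.
* The Fst experiments use the 3-case vs 24-control design with 50 kb
  windows in 10 kb steps.
* CNV recovery plants homozygous deletions of 7245 bp and 21,284 bp (the
  sizes of the two known pony-specific deletions) on a 500 bp window grid
  at a mean of 50 reads per window.
* The association cohort has 243 phenotyped individuals and four causal
  loci with additive effects summing to -9.24 cm (an 18.48 cm span between
  the all-wild-type and all-mutant homozygotes), residual sd 3 cm.
  Genotypes at each locus are drawn (0.45, 0.10, 0.45) over codes (0,1,2):
  a validation panel mixing near-fixed miniature lines with near-fixed
  control breeds is dominated by the two homozygote classes, and this
  homozygote enrichment (genotype variance 0.8 vs the Hardy-Weinberg
  ceiling of 0.5) is what gives the effect-sum estimate its precision at
  this sample size.  Loci are independent, matching the weak inter-locus
  LD observed for the real variants.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .cnv_detect import DepthTrack, call_cnvs
from .fst_scan import top_percentile, windowed_fst
from .genomics_io import GenomicInterval
from .roh_scan import RohParams, call_roh
from .synthetic_data import (
    CausalLocus,
    CnvEvent,
    SimulationConfig,
    simulate_genotypes,
    simulate_read_depth,
    simulate_trait,
)
from .trait_assoc import fit_joint_additive


def _seed_for(seed: int, rep: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt, rep]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------- ROH ----


def roh_recovery_rate(
    n_reps: int = 100,
    seed: int = 0,
    min_reciprocal_overlap: float = 0.9,
    tract_mb_range: Tuple[float, float] = (0.28, 3.34),
) -> float:
    """Fraction of replicates in which a planted het-free autozygous tract
    is recovered by a called segment with the given reciprocal overlap."""
    size_rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    hits = 0
    for rep in range(n_reps):
        length = int(size_rng.uniform(*tract_mb_range) * 1e6)
        chrom_len = length + 1_200_000
        truth = GenomicInterval("1", 600_000, 600_000 + length - 1)
        cfg = SimulationConfig(
            n_cases=1,
            n_controls=0,
            chromosome_lengths={"1": chrom_len},
            snps_per_chromosome=chrom_len // 1000,
            planted_roh=[(("case1",), truth)],
            seed=_seed_for(seed, rep, 1),
        )
        gm = simulate_genotypes(cfg)
        for seg in call_roh(gm, "case1", RohParams()):
            ov = seg.interval.overlap_bp(truth)
            if (
                ov >= min_reciprocal_overlap * truth.length_bp
                and ov >= min_reciprocal_overlap * seg.length_bp
            ):
                hits += 1
                break
    return hits / n_reps


# ---------------------------------------------------------------- Fst ----


def fst_null_experiment(
    seed: int = 0, n_windows: int = 1000
) -> Tuple[float, float]:
    """Mean and standard error of window Fst when case and control share
    every allele frequency (3 vs 24 samples).

    Uses non-overlapping 50 kb windows so the windows are independent and
    the standard error of their mean is well defined; sliding windows
    (10 kb step) share 80% of their SNPs and would understate it.
    """
    chrom_len = n_windows * 50_000
    cfg = SimulationConfig(
        n_cases=3,
        n_controls=24,
        chromosome_lengths={"1": chrom_len},
        snps_per_chromosome=chrom_len // 1000,
        seed=_seed_for(seed, 0, 2),
    )
    gm = simulate_genotypes(cfg)
    windows = windowed_fst(
        gm,
        cfg.case_ids,
        cfg.control_ids,
        window_bp=50_000,
        step_bp=50_000,
        chromosome_lengths=cfg.chromosome_lengths,
    )
    values = np.array([w.fst for w in windows])
    values = values[~np.isnan(values)]
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(len(values)))


def fst_divergent_block_hit_rate(n_reps: int = 10, seed: int = 0) -> float:
    """Fraction of replicates where every window fully inside a planted
    divergent block (case 0.95 vs control 0.05) clears the top-1%
    threshold."""
    chrom_len = 20_050_000  # ~2000 windows, so the 1% tail holds the block
    block = GenomicInterval("1", 2_000_001, 2_100_000)
    hits = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_cases=3,
            n_controls=24,
            chromosome_lengths={"1": chrom_len},
            snps_per_chromosome=chrom_len // 1000,
            divergent_loci=[(block, 0.95, 0.05)],
            seed=_seed_for(seed, rep, 3),
        )
        gm = simulate_genotypes(cfg)
        windows = windowed_fst(
            gm, cfg.case_ids, cfg.control_ids, chromosome_lengths=cfg.chromosome_lengths
        )
        threshold, _ = top_percentile(windows, 0.99)
        inside = [
            w
            for w in windows
            if w.interval.start >= block.start and w.interval.end <= block.end
        ]
        if inside and all(w.fst >= threshold for w in inside):
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------- CNV ----

DELETION_SIZES_BP = (7245, 21_284)


def cnv_deletion_recovery(
    n_reps: int = 100,
    seed: int = 0,
    window_size: int = 500,
    depth_mean: float = 50.0,
    max_breakpoint_error_windows: int = 2,
) -> Tuple[float, Dict[int, float]]:
    """Plant homozygous (cn=0) deletions of the two known sizes and measure
    how often both are recovered as loss calls with breakpoint error within
    the window tolerance.

    Returns (recovery_rate, {true_size: mean estimated size in bp}).
    """
    chrom_len = 120_000
    tol_bp = max_breakpoint_error_windows * window_size
    offset_rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    hits = 0
    est_sizes: Dict[int, List[int]] = {s: [] for s in DELETION_SIZES_BP}
    for rep in range(n_reps):
        starts = (20_000, 60_000)
        events = []
        for s0, size in zip(starts, DELETION_SIZES_BP):
            start = s0 + int(offset_rng.integers(0, window_size))
            events.append(CnvEvent(GenomicInterval("1", start, start + size - 1), 0))
        cfg = SimulationConfig(
            chromosome_lengths={"1": chrom_len},
            cnv_events=events,
            read_depth_mean=depth_mean,
            seed=_seed_for(seed, rep, 4),
        )
        t = simulate_read_depth(cfg, window_size)["1"]
        track = DepthTrack(
            chromosome="1",
            window_start=t["window_start"],
            window_size=window_size,
            case_count=t["case"],
            control_count=t["control"],
        )
        calls = [c for c in call_cnvs(track) if c.direction == "loss"]
        ok = 0
        for event, size in zip(events, DELETION_SIZES_BP):
            for c in calls:
                if (
                    abs(c.interval.start - event.interval.start) <= tol_bp
                    and abs(c.interval.end - event.interval.end) <= tol_bp
                ):
                    est_sizes[size].append(c.interval.length_bp)
                    ok += 1
                    break
        if ok == len(events):
            hits += 1
    mean_sizes = {
        s: float(np.mean(v)) if v else float("nan") for s, v in est_sizes.items()
    }
    return hits / n_reps, mean_sizes


# ---------------------------------------------------------- association ----

COHORT_EFFECTS_CM = (-2.0, -1.5, -3.0, -2.74)
COHORT_LOCI = ("ADAMTS17", "OSTN", "GH1", "HMGA2")
#: genotype-class probabilities for codes (0, 1, 2) in the validation panel
COHORT_GENO_PROBS = (0.45, 0.10, 0.45)


def simulate_association_cohort(
    seed: int, n: int = 243, trait_sd: float = 3.0
) -> list:
    """One phenotyped cohort under the four-locus additive architecture."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    loci = [CausalLocus(l, a) for l, a in zip(COHORT_LOCI, COHORT_EFFECTS_CM)]
    genos = {
        f"p{i + 1}": {
            l.name: int(rng.choice(3, p=COHORT_GENO_PROBS)) for l in loci
        }
        for i in range(n)
    }
    return simulate_trait(genos, loci, trait_mean=100.0, trait_sd=trait_sd, seed=seed)


def joint_model_recovery(
    n_reps: int = 200, seed: int = 0, tolerance_cm: float = 1.5
) -> Tuple[float, float]:
    """Fraction of cohort replicates whose joint-model effect-sum span
    |2*sum(a_k)| lands within tolerance of the true 18.48 cm, plus the
    first replicate's estimate."""
    truth = abs(2.0 * sum(COHORT_EFFECTS_CM))
    hits = 0
    first_estimate = float("nan")
    for rep in range(n_reps):
        records = simulate_association_cohort(_seed_for(seed, rep, 5))
        model = fit_joint_additive(records, list(COHORT_LOCI))
        if rep == 0:
            first_estimate = model.total_reduction_cm
        if abs(model.total_reduction_cm - truth) <= tolerance_cm:
            hits += 1
    return hits / n_reps, first_estimate
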