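"""Synthetic diploid populations with planted structure.

Generates the inputs every downstream stage consumes, with known ground
truth: genotype matrices with planted autozygous tracts and divergent
case/control loci, quantitative traits built from additive (and optional
dominance) effects at causal loci, and Poisson read-depth tracks carrying
copy-number losses and gains.

The default configuration mirrors a small-cohort resequencing design: a
handful of case genomes against a pool of two dozen controls, four causal
loci with size-reducing additive effects, and homozygous deletions a few kb
long.  Loci are simulated independently (no background linkage
disequilibrium); all planted structure is explicit so tests can assert
recovery against truth.

Randomness is driven by a single integer seed; each generator call splits
its own independent stream via ``numpy.random.SeedSequence`` so adding one
simulation never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomics_io import GenomicInterval, GenotypeMatrix, TraitRecord, VariantSite

_ALLELES = ("A", "C", "G", "T")


@dataclass
class CausalLocus:
    """A trait-affecting locus: additive effect per counted allele (cm) and
    dominance deviation of the heterozygote (cm)."""

    name: str
    additive_cm: float
    dominance_cm: float = 0.0


@dataclass
class CnvEvent:
    interval: GenomicInterval
    copy_number: int  # 0,1 loss; 3,4 gain (2 = no event)

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 2, 3, 4):
            raise ValueError(f"copy number {self.copy_number} not in 0..4")


@dataclass
class SimulationConfig:
    """Study-design parameters for the generators.

    Defaults emulate the small-cohort design the pipeline targets: 3 case
    genomes vs a pool of 24 controls, ~1 SNP/kb marker density, allele
    frequencies from a U-shaped Beta(0.5, 0.5), and a 5 cm trait standard
    deviation around a 100 cm mean.
    """

    n_cases: int = 3
    n_controls: int = 24
    chromosome_lengths: Dict[str, int] = field(
        default_factory=lambda: {"1": 2_000_000, "2": 2_000_000}
    )
    snps_per_chromosome: int = 2000
    freq_beta_a: float = 0.5
    freq_beta_b: float = 0.5
    planted_roh: List[Tuple[Tuple[str, ...], GenomicInterval]] = field(default_factory=list)
    divergent_loci: List[Tuple[GenomicInterval, float, float]] = field(default_factory=list)
    causal_loci: List[CausalLocus] = field(default_factory=list)
    trait_mean_cm: float = 100.0
    trait_sd_cm: float = 5.0
    cnv_events: List[CnvEvent] = field(default_factory=list)
    read_depth_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_sd_cm < 0:
            raise ValueError("trait_sd must be >= 0")
        for _, p_case, p_ctrl in self.divergent_loci:
            if not (0 <= p_case <= 1 and 0 <= p_ctrl <= 1):
                raise ValueError("divergent-locus frequencies must be in [0,1]")

    @property
    def case_ids(self) -> List[str]:
        return [f"case{i + 1}" for i in range(self.n_cases)]

    @property
    def control_ids(self) -> List[str]:
        return [f"ctrl{i + 1}" for i in range(self.n_controls)]


def _streams(seed: int, n: int, label: str) -> list:
    """Independent generators derived from one seed, namespaced by label
    (stable CRC32 of the label, so streams are reproducible across runs)."""
    import zlib

    root = np.random.SeedSequence([seed, zlib.crc32(label.encode()) % (2**31)])
    return [np.random.default_rng(s) for s in root.spawn(n)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a case+control genotype matrix with planted ROH tracts and
    divergent loci.

    Background genotypes are Binomial(2, f) per locus with locus frequencies
    from Beta(a, b).  Inside a planted ROH interval the listed samples are
    forced homozygous (alt-hom with probability equal to the local allele
    frequency, otherwise ref-hom).  Inside a divergent interval the per-locus
    alt frequency is the configured case or control frequency.
    """
    (rng,) = _streams(config.seed, 1, "genotypes")
    sample_ids = config.case_ids + config.control_ids
    n_samples = len(sample_ids)
    case_set = set(config.case_ids)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    # reject contradictory planted ROH (same sample, overlapping interval)
    for i, (samples_i, iv_i) in enumerate(config.planted_roh):
        for samples_j, iv_j in config.planted_roh[i + 1 :]:
            if set(samples_i) & set(samples_j) and iv_i.overlaps(iv_j):
                raise ValueError(
                    f"overlapping planted ROH for shared samples: {iv_i} / {iv_j}"
                )

    is_case = np.array([s in case_set for s in sample_ids])

    variants: List[VariantSite] = []
    blocks: List[np.ndarray] = []
    for chrom in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[chrom]
        n_snps = min(config.snps_per_chromosome, length)
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=n_snps, replace=False)
        ).astype(np.int64)
        freqs = rng.beta(config.freq_beta_a, config.freq_beta_b, size=n_snps)
        p_case = freqs.copy()
        p_ctrl = freqs.copy()
        for iv, pc, pk in config.divergent_loci:
            if iv.chromosome == chrom:
                m = (positions >= iv.start) & (positions <= iv.end)
                p_case[m] = pc
                p_ctrl[m] = pk
        prob = np.where(is_case[:, None], p_case[None, :], p_ctrl[None, :])
        block = rng.binomial(2, prob).astype(np.int8)
        for samples, iv in config.planted_roh:
            if iv.chromosome != chrom:
                continue
            m = (positions >= iv.start) & (positions <= iv.end)
            for s in samples:
                i = sample_pos[s]
                p = prob[i, m]
                block[i, m] = (2 * (rng.random(m.sum()) < p)).astype(np.int8)
        ref = rng.integers(0, 4, size=n_snps)
        alt = (ref + rng.integers(1, 4, size=n_snps)) % 4
        for j in range(n_snps):
            variants.append(
                VariantSite(
                    chrom,
                    int(positions[j]),
                    _ALLELES[ref[j]],
                    _ALLELES[alt[j]],
                    qual=99.0,
                )
            )
        blocks.append(block)

    calls = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((n_samples, 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, variants, calls)


def simulate_trait(
    genotypes: Dict[str, Dict[str, int]],
    causal_loci: Sequence[CausalLocus],
    trait_mean: float,
    trait_sd: float,
    seed: int,
) -> List[TraitRecord]:
    """Quantitative trait from an additive + dominance architecture.

    height_i = mean + sum_k a_k (g_ik - 1) + d_k [g_ik == 1] + eps_i,
    eps ~ Normal(0, sd^2).  ``genotypes`` maps sample -> {locus: code};
    samples missing any causal genotype are dropped with a warning.
    """
    import warnings

    (rng,) = _streams(seed, 1, "trait")
    records: List[TraitRecord] = []
    for sample_id in genotypes:
        codes = genotypes[sample_id]
        if any(codes.get(l.name, -1) == -1 for l in causal_loci):
            warnings.warn(f"sample {sample_id} missing a causal genotype; dropped")
            continue
        value = trait_mean
        for locus in causal_loci:
            g = codes[locus.name]
            value += locus.additive_cm * (g - 1)
            if g == 1:
                value += locus.dominance_cm
        value += rng.normal(0.0, trait_sd)
        records.append(
            TraitRecord(
                sample_id=sample_id,
                height_cm=float(value),
                genotypes=dict(codes),
            )
        )
    return records


def genotype_table(matrix: GenotypeMatrix, loci: Dict[str, Tuple[str, int]]) -> Dict[str, Dict[str, int]]:
    """Extract {sample: {locus_name: code}} for named (chrom, pos) loci."""
    idx = {}
    for name, (chrom, pos) in loci.items():
        hits = [
            j
            for j, v in enumerate(matrix.variants)
            if v.chromosome == chrom and v.position == pos
        ]
        if not hits:
            raise KeyError(f"locus {name} at {chrom}:{pos} not in matrix")
        idx[name] = hits[0]
    return {
        s: {name: int(matrix.calls[i, j]) for name, j in idx.items()}
        for i, s in enumerate(matrix.sample_ids)
    }


def simulate_cohort_genotypes(
    n_samples: int,
    loci: Sequence[CausalLocus],
    freqs: Sequence[float],
    seed: int,
) -> Dict[str, Dict[str, int]]:
    """Independent Binomial(2, f) genotypes at the causal loci for a
    phenotyping cohort (no genome-wide marker panel needed)."""
    (rng,) = _streams(seed, 1, "cohort")
    out: Dict[str, Dict[str, int]] = {}
    for i in range(n_samples):
        out[f"p{i + 1}"] = {
            locus.name: int(rng.binomial(2, f)) for locus, f in zip(loci, freqs)
        }
    return out


def simulate_read_depth(
    config: SimulationConfig, window_size: int
) -> Dict[str, dict]:
    """Per-window Poisson read counts for the case and control tracks.

    Control windows draw Poisson(lambda); case windows inside a planted CNV
    draw Poisson(lambda * cn / 2) — proportionally reduced where a window
    only partially overlaps the event — and Poisson(lambda) elsewhere.

    Returns {chrom: {"window_start": array, "case": array, "control": array,
    "window_size": int}}.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    lam = config.read_depth_mean
    if lam <= 0:
        raise ValueError("read_depth_mean must be > 0")
    (rng,) = _streams(config.seed, 1, "depth")
    tracks: Dict[str, dict] = {}
    for chrom in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[chrom]
        starts = np.arange(1, length + 1, window_size, dtype=np.int64)
        n_win = len(starts)
        control = rng.poisson(lam, size=n_win)
        case_lam = np.full(n_win, lam, dtype=float)
        for event in config.cnv_events:
            if event.interval.chromosome != chrom:
                continue
            ends = np.minimum(starts + window_size - 1, length)
            ov_lo = np.maximum(starts, event.interval.start)
            ov_hi = np.minimum(ends, event.interval.end)
            frac = np.clip(ov_hi - ov_lo + 1, 0, None) / (ends - starts + 1)
            case_lam = case_lam * (1 - frac) + case_lam * frac * (event.copy_number / 2)
        case = rng.poisson(case_lam)
        tracks[chrom] = {
            "window_start": starts,
            "case": case,
            "control": control,
            "window_size": window_size,
        }
    return tracks


def write_vcf(matrix: GenotypeMatrix, path, depth: int = 30) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT and DP fields."""
    code_to_gt = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in matrix.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            qual = "." if np.isnan(v.qual) else f"{v.qual:.1f}"
            samples = "\t".join(
                f"{code_to_gt[int(c)]}:{depth}" for c in matrix.calls[:, j]
            )
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t{qual}\t.\t.\tGT:DP\t{samples}\n"
            )


def write_depth_tsv(tracks: Dict[str, dict], path) -> None:
    """Write read-count tracks as TSV (chrom, window_start, case, control)."""
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start\twindow_size\tcase_count\tcontrol_count\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for s, c, k in zip(t["window_start"], t["case"], t["control"]):
                fh.write(f"{chrom}\t{s}\t{t['window_size']}\t{c}\t{k}\n")
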