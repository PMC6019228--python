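# Methods

This note documents the models implemented in `miniscan`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was open.

## Coordinates and genotype coding

All internal coordinates are 1-based inclusive; conversion to 0-based
half-open happens only at the BED file boundary. Genotypes are coded
0 (hom-ref), 1 (het), 2 (hom-alt), −1 (missing). VCF input keeps biallelic
SNVs only; per-sample calls with FORMAT/DP outside [3, 60] are set missing
and sites with QUAL < 20 are dropped (the conventional confident-SNP
filter for ~20× resequencing data; the depth filter is applied per sample
because site-level DP would mask sample-specific coverage failures).
Chromosome X and unplaced contigs are excluded by default from autosomal
scans, with a flag to include them.

## Runs of homozygosity

The caller is the two-pass window-threshold scan popularised by PLINK's
`--homozyg`:

1. Slide a window of `window_snps` = 50 consecutive SNPs. A window is
   *homozygous* if it contains ≤ 3 heterozygous and ≤ 10 missing calls.
   Each SNP is flagged if the fraction of overlapping homozygous windows
   is ≥ `window_hit_threshold` = 0.05 (the conventional default; the other
   parameters are the standard resequencing settings).
2. Maximal runs of flagged SNPs are split wherever consecutive SNPs are
   > 100 kb apart, then filtered: ≥ 50 SNPs, ≥ 150 kb, mean spacing ≤ 3
   kb/SNP (interpreted as a segment-level density bound). Segment
   boundaries are the first/last SNP positions of the run.

**Boundary precision.** The window-threshold design trades boundary
sharpness for robustness: SNPs just outside a true autozygous tract are
still covered by windows reaching back into it, so calls extend ~10–15 kb
per side at 1 SNP/kb density (a fraction of the window span), independent
of tract length. Consequently 90% reciprocal-overlap recovery is essentially
perfect for tracts ≳ 0.5 Mb but degrades toward the 0.3 Mb scale. The
recovery experiment in `evaluation.py` plants tract lengths drawn uniformly
from 0.28–3.34 Mb — the observed size range of candidate-region ROHs in
small-pony selection scans — and recovers ≥ 95% of them.

Shared regions are the exact base-pair intersection of merged per-sample
ROH coverage across *all* required samples (not pairwise overlap), verified
against a per-base bitmap oracle. `genome_fraction` is Σ merged region
lengths / Σ chromosome lengths.

## Dating selection from tract length

Recombination erodes a haplotype of genetic length *c* Morgans in about
1/(2c) generations. With a uniform map of 1 cM/Mb (configurable), a tract
of *L* Mb gives c = L/100, age = 50/L generations, and years = generations
× a 10-year generation interval (the convention for horse populations).
Full precision is kept internally; reported values round to 2 decimals,
with years computed from the unrounded generation number. The product
age × L is constant (50 generations·Mb at 1 cM/Mb), which the property
tests exploit.

## Windowed Hudson Fst

Per SNP, allele frequencies p₁, p₂ are computed from non-missing genotypes
(n₁, n₂ allele copies; SNPs with fewer than 2 copies in either group are
skipped). The Hudson components with finite-sample correction are

    N̂ = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    D̂ = p₁(1−p₂) + p₂(1−p₁)

and a window's Fst is Σ N̂ / Σ D̂ over its SNPs (ratio of averages).
Hudson's estimator was chosen deliberately for its robustness to very
unequal sample sizes (3 cases vs 24 pooled controls); ratio-of-averages
windowing avoids the instability of averaging per-SNP ratios. E[N̂] = 0
under equal frequencies, so window values scatter around zero and are
*not* clamped — negative estimates are reported as-is because clamping
would distort the empirical percentile. Windows with no informative SNP
get NaN and are excluded from quantiles. The scan tiles 50 kb windows in
10 kb steps from position 1 of each chromosome; percentile selection uses
the linear-interpolated empirical quantile and returns windows at or above
the threshold. Merging selected windows into regions is provided as a
separate optional step, since "region" counts can be read either way.

For *calibration* experiments the null mean is measured on non-overlapping
50 kb windows: sliding windows share 80% of their SNPs, which makes the
naive standard error of the window mean meaningless. The divergent-block
experiment scans ~2000 windows so that the 1% tail (20 windows) is larger
than the ~10 windows touching a 100 kb block; on smaller scans the
"every block window in the top 1%" property is arithmetically impossible.

## Variant screening

Two parallel routes operate on variants inside shared ROH regions. The
functional route keeps variants annotated HIGH or MODERATE (join key:
chromosome, position, alt allele; unannotated variants are dropped with a
logged count; duplicate annotations are an error). Deleteriousness
(SIFT-style score < 0.05) is carried as metadata rather than used as a
hard filter, mirroring the two-route design. The exclusivity route keeps
variants where every case is homozygous alternate and every control
homozygous reference; a missing call in any required sample disqualifies
the variant — the strict reading, because false positives are costlier
than false negatives in a candidate screen. Samples of unclear phenotype
(e.g. ancient genomes) can be excluded from both groups before testing.

## Read-depth CNV calling

Counts live on a fixed non-overlapping window grid (default 500 bp; tools
that derive window size from total read counts are not reproducible
without controlling those totals, so the size is explicit here). The
per-window statistic is

    log2( (case + 0.5) / (control + 0.5) × total_control / total_case )

with a 0.5 pseudocount so homozygous deletions (zero case reads) stay
finite. Calls are maximal runs of ≥ 10 consecutive windows all beyond
±0.7; each run's significance comes from the Geary–Hinkley normal
approximation to the Poisson count ratio per window (using genome-wide
mean window counts as the null means), combined across the run by
Stouffer's method, and runs with p ≥ 0.001 are discarded. Strict
consecutive runs are slightly more conservative than tools that bridge
sub-threshold gaps: one noisy window splits a run, so reliable detection
of *heterozygous* losses (true |log2| = 1, only 0.3 above threshold)
needs per-window depth high enough that the noise sd (≈1.44·√(1/λc+1/λk))
is well under the 0.3 margin. Homozygous deletions sit ~6 log2 units below
threshold and are insensitive to this. Zygosity is classified from the
mean log2 ratio: ≤ −2.5 homozygous loss, [−1.5, −0.7] heterozygous loss,
≥ 0.7 gain, otherwise ambiguous.

CNVRs intersect per-pairing call lists: every pairing must contribute a
call of the same direction (mixing a loss with a gain is biologically
incoherent) and the common intersection must be ≥ 50 bp. The operation is
commutative over pairings and is verified against a per-base AND oracle.

## Genotype–trait association

The per-locus model is one-way fixed-effects OLS with genotype as a
categorical factor — R² = SS_model/SS_total, F with (k−1, n−k) df,
least-squares means equal to class means with SE = s·√(1/n_class) from the
pooled residual s. (No random terms are fitted; the single-factor design
fully determines these statistics.) The joint model regresses the trait on
per-locus allele counts, optionally adding heterozygote indicators for
loci with suspected dominance, and reports the effect-sum span
|2·Σaₖ| — the expected trait difference between the all-wild-type and
all-mutant homozygotes. Rank-deficient designs raise an error naming the
collinear loci. LD between loci is the squared Pearson correlation of
allele-count vectors over samples complete at both loci (undefined and
reported as missing when a locus is monomorphic). P-values are reported
raw; Bonferroni correction across loci is available but not applied by
default.

The miniature classifier is the synergy rule: a four-locus genotype is
miniature-consistent iff all four loci are homozygous mutant, or three are
homozygous mutant and the fourth heterozygous — exactly 5 of the 81
possible genotype combinations, verified by exhaustive enumeration. The
ceiling check lists classifier-positive individuals taller than 87 cm; an
empty list means the size-ceiling claim holds on the dataset.

## Synthetic data: what it emulates, and what it does not

The generator draws per-locus allele frequencies from Beta(0.5, 0.5) (a
U-shaped spectrum typical of resequencing panels) and genotypes
independently per sample as Binomial(2, f). Planted structure is explicit:
autozygous tracts force listed samples homozygous (alt with probability
equal to the local frequency); divergent intervals give cases and controls
different frequencies; causal loci add aₖ·(g−1) + dₖ·I[g=1] to a Gaussian
trait; copy-number events scale the Poisson read-depth mean by cn/2
(proportionally for partially covered windows). A single integer seed
drives everything through namespaced `SeedSequence` streams, so adding one
simulation never perturbs another and every generator is bit-reproducible.

Deliberately absent: background linkage disequilibrium, mutation/
recombination history (no coalescent), read-level error, GC or mappability
bias in depth tracks, and population structure beyond the planted
case/control frequency differences. Passing tests therefore demonstrate
that each algorithm recovers the structure it is designed to detect under
its own statistical assumptions — not that those assumptions hold in any
particular real cohort.

The association-cohort generator (`evaluation.py`) fixes n = 243
phenotyped individuals, additive effects (−2.0, −1.5, −3.0, −2.74) cm
summing to a 18.48 cm homozygote span, residual sd 3 cm, and per-locus
genotype probabilities (0.45, 0.10, 0.45) over codes (0, 1, 2). The
homozygote enrichment reflects a validation panel mixing near-fixed
miniature lines with near-fixed control breeds: it raises the per-locus
genotype variance to 0.8, above the Hardy–Weinberg ceiling of 0.5, and a
power computation (sd of the effect-sum span = 4σ/√(n·Var(g))) shows this
is what makes the span recoverable to ±1.5 cm in ≥ 90% of cohorts at this
sample size — under Hardy–Weinberg proportions it would not be. Loci are
independent, consistent with the weak inter-locus LD of the real variants.

## Problem sizes used in experiments

Recovery experiments run at desk scale: ROH recovery on single ~1.5–4.5 Mb
chromosomes at 1 SNP/kb (100 replicates); Fst null on 1000 independent
50 kb windows and block detection on ~2000 sliding windows (10
replicates); CNV recovery on a 120 kb track at λ = 50 per 500 bp window
(100 replicates); association on 200 cohort replicates of n = 243. These
sizes were chosen so the full suite and the reproduction script each run
in well under a minute while keeping every rate estimate's binomial error
a few percent.

## Known limitations

- ROH boundary fuzz (above) makes sub-0.4 Mb tract boundaries imprecise.
- The exact end-of-chromosome window handling of legacy ROH callers is
  not uniquely specified; windows here are evaluated only where a full
  window of SNPs exists, and chromosomes with fewer SNPs than one window
  yield no calls.
- CNV run-calling does not bridge sub-threshold gaps; fragmented calls on
  marginal (heterozygous) events at low depth are expected.
- The Fst estimator operates on called genotypes; genotype-likelihood
  methods for low-coverage data are out of scope.
- No kinship or population-structure correction in the association models.
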