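# Methods

## The assay being modelled

A promoter capture panel (hundreds of capture regions partitioning
promoter-spanning primary target regions, nominally −1500/+500 around a
transcription start site) is sequenced after bisulfite conversion, paired-end,
to a mean on-target depth of roughly 190x. Unmethylated cytosines read as T
(bottom strand: G reads as A); 5-methylcytosine is protected and reads as C.
Because the two strands are no longer complementary after conversion,
methylation is called per strand: original-top (OT) reads inform the C of
each CpG, original-bottom (OB) reads inform the G position (the
bottom-strand cytosine). An unmethylated lambda phage spike-in measures
conversion failure.

## Methylation calling

Pairs are kept only if mapped, properly paired and not flagged duplicate.
Where mates overlap, the overlapping bases of the rightmost mate are
discarded so a fragment contributes at most one call per genomic base. For
every reference CpG cytosine within a capture region ± `flank` (default
250 bp), the methylation ratio is meth/(meth+unmeth) counting C vs T on the
+ strand from OT reads and G vs A on the − strand from OB reads; other
bases (sequencing errors) are ignored. Sites are reported per cytosine,
methratio-style (two rows per CpG dinucleotide); region statistics pool both
strands as separate sites. No base- or mapping-quality filter is applied.

Conversion efficiency is T/(C+T) × 100 over *all* lambda reference
cytosines, both strands — not only CpGs — since the control is fully
unmethylated. Sensitivity is (1/depth) × 100, rounded half-up to two
decimals (0.53% at 189.6x); it is the allele fraction at which a single
read is expected to carry the signal.

## Region matrix

A CpG enters the analysis only with depth ≥ `min_depth` (default 10) in
every sample; this is the matrix's missingness mechanism — a region with no
qualifying CpG is missing in all samples. A region's value is the
unweighted mean of qualifying per-CpG ratios within region ± flank. Flanking
CpGs are included both in selection and in the mean (configurable); note
that where a flank reaches into a neighbouring capture region this mixes
the neighbour's signal into the mean — visible as dilution of sharp
single-region effects in multi-region genes.

The strict "depth > 10 and ratio > 0" filter is used only for the
informative-CpG QC count; the matrix uses the ≥ 10 rule, which governs the
analysis.

## Minority differential methylation

Per region, values are standardized across samples (sample sd, n−1). A
sample is an outlier when |z| exceeds the two-sided standard-normal
quantile at the confidence level (2.5758 at 99%; the reference distribution
is assumed normal). A region is called when the outlier count lies in
[1, ⌈n/3⌉] — for n = 34, at most 12 — a minority departing from a stable
majority. Direction is positive/negative when all outliers share a sign,
mixed otherwise; mixed regions are called but excluded from the
hyper-methylated subset. Z-scores are computed on the raw (unimputed)
matrix, dropping missing samples per region; regions with fewer than 3
observed values or zero spread are non-assessable.

A structural detectability bound worth knowing: if a minority of k samples
sits at one shifted level and the majority at another (tight scatter), the
minority's |z| is √((n−k)(n−1)/(kn)) regardless of effect size. At 99%
confidence this exceeds 2.5758 only for k ≤ 4 when n = 34 (and requires
n ≥ 9 even for k = 1). Synthetic minorities larger than that are invisible
to the rule by construction; real data escape the bound only through
within-majority biological scatter. Recovery tests therefore plant
minorities of 1-3 samples.

Effect sizes are reported as extremes across samples: percent-point
difference (max − min) × 100 and fold change max/min, undefined (NaN) when
the minimum is exactly 0. Fold is computed from unrounded means; recomputing
from rounded published values can disagree in the last printed digit. No
multiple-testing correction is applied (none is part of the procedure).

## Clustering and reproducibility

Missing region values are imputed before clustering by k-nearest-neighbour
regions (k = 10, the classic microarray imputer's default): distance
between two region rows is the root-mean-square difference over columns
observed in both, and the imputed cell is the mean of the k nearest rows
observed at that column. Observed cells are never altered.

Both axes of the Z-score matrix are clustered by average linkage under
correlation distance 1 − Pearson r (Spearman available); constant rows or
columns have undefined correlation and are dropped with a warning. Samples
are split at the top of the tree into two clusters. Gene groups A and B —
the paperless operationalization of "regions high in one cluster, low in
the other" — are regions whose cluster-wise mean Z differs by more than
`contrast` (default 1, in Z units), signed so A is high in cluster 1.

Per-sample overall methylation outliers use the interval for individual
observations: cohort mean ± z₀.₉₇₅ × sd of the per-sample means at 95%.

Assay reproducibility is the CV% (sd/mean × 100, n−1 sd) of region means
across replicate runs, undefined at zero mean; the randomized-subset
variant represents a region by `subset_size` (default 5) randomly drawn
CpGs per round (default 5 rounds, seeded) and quantifies the variability
inflation from sparse CpG sampling.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
raw sequencer output:

- **Panel/reference.** One contig per gene; a promoter-like primary region
  split into 1+ contiguous capture regions (lengths drawn from a range);
  CpG dinucleotides planted every ~30 bp across the span and flanks,
  elsewhere suppressed so all CpGs are at known positions. The lambda
  contig has natural base composition.
- **Cohort truth.** Region baselines drawn from a low-skewed beta
  (Beta(0.6, 1.6) — promoter methylation in blood is mostly low with a
  methylated tail); per-sample scatter is beta-distributed around the
  baseline with sd ≈ 0.01 by default (the within-majority variance of
  stable regions is a free parameter; the default keeps null regions null).
  Differential regions shift a chosen minority (≤ ⌈n/3⌉) by a fixed
  percent-point effect, hyper or hypo, with feasibility (level ∈ [0,1])
  validated.
- **Reads.** Fragments are laid uniformly over the union of capture regions
  ± flank (merged per contig); the pair count is calibrated so post-filter
  depth matches the target (realized depth lands within ~1%). Methylation
  is drawn **per fragment per CpG** (Bernoulli at the truth level), so
  mosaic alleles are representable; each CpG inherits the level of its
  nearest capture region. Unmethylated cytosines convert with probability
  `conversion_eff` (default 0.995); sequencing errors substitute uniformly
  at `seq_error` (default 0.001); duplicates are exact positional copies
  flagged as such (default rate 0.05); small fractions of improper (0.02)
  and unmapped (0.005) pairs exercise the filters. Reads are generated
  already aligned — alignment, trimming and FASTQ are out of scope, so
  mapping loss exists only as flags.
- **Fast surrogate.** `simulate_region_means` samples region means directly
  (mean of n_cpgs Binomial(depth, level)/depth draws), sharing the
  read-level sampling distribution under perfect conversion; cohort-scale
  recovery experiments use it to stay within seconds.

What a green test establishes: the pipeline recovers planted effects under
binomial sampling noise, jitter, duplicates and imperfect conversion. What
it does not: robustness to alignment artifacts, SNPs overlapping CpGs,
quality-dependent errors, or leukocyte-composition confounding — none are
modelled.

## Numerical choices

- Coordinates 0-based half-open internally, BED on disk, 1-based in
  methratio-style TSV.
- Sensitivity rounded half-up (decimal arithmetic) to 2 decimals.
- Constant rows detected exactly (max == min), not via sd == 0, to dodge
  floating-point sd ~ 1e-17 on constant input.
- Z matrix rows standardize to mean 0, sd 1 within 1e-9 (tested).
- Imputer ties broken by stable argsort; linkage tie-breaking follows
  scipy, so oracle comparisons use sorted merge heights.
- Seeds: every generator takes an explicit seed; the pipeline derives
  stage seeds as seed, seed+1, seed+2 and records the base seed in its
  summary JSON.

## Known limitations

- Minority sizes above the detectability bound (see above) cannot be
  called on tight-jitter synthetic data at 99% confidence — an inherent
  property of z-scores in small cohorts, not a defect of the caller.
- Coverage accounting reports `pct_post_qc` = 100 because quality trimming
  happens upstream of this pipeline's inputs.
- Heatmap rendering is not included; linkage trees (Newick), cluster labels
  and group A/B lists are exported for external plotting/enrichment.
- Replicate CV values from the published assay (mean 7.1%, median 4.4%)
  depend on raw replicate data that is not available; the reproducibility
  module is validated against binomial theory and planted simulations
  instead.
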