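# Methods

## Model and scope

dmrkit tests for regional shifts in cytosine-modification levels between
two conditions. The unit of inference is the methylated region (MR): a
spatial cluster of modified sites inside one annotated genomic region.
Testing regions rather than single CpGs reflects two assumptions: that
regulatory methylation changes span clusters of nearby CpGs, and that
per-site sampling noise (finite coverage) makes single-site calls
unreliable. The method makes no distributional assumption about levels
when the rank-sum or KS test is used; the *t*-test path assumes
approximate normality of levels within an MR.

Input levels are tag-count ratios for HMST-seq (unbounded, ~1 at a neutral
site) or methylation fractions in [0, 1] for WGBS/RRBS. Levels are treated
as exchangeable within an MR; coverage is not used as a weight (a
beta-binomial treatment is out of scope).

## Coordinates and region extraction

All intervals are 0-based half-open, matching BED and UCSC refFlat.
Per transcript row (multiple transcripts of a gene are processed
independently, duplicates removed afterwards):

* TSS region `[tss − f, tss + f)` with flank `f` = 1000 bp; TES likewise.
  The TSS point is `txStart` on '+' and `txEnd` on '−'.
* Gene body: the interval strictly between the two flank regions. Genes
  shorter than the two flanks have no definable body; their flank regions
  are kept and the omission is logged.
* 5′ distance: 10–100 kb upstream of the TSS, strand-aware (on '−' genes
  this extends to higher coordinates).
* Intergenic: per-chromosome complement of the union of all TSS/TES/gene
  body regions. Segments shorter than 2 kb are dropped. Segments longer
  than 100 kb are truncated to their first 100 kb by default, preserving
  coverage adjacent to genes; `intergenic_mode="split"` instead chunks the
  whole segment into consecutive ≤100 kb pieces.
* 5′ distance windows are *not* subtracted from intergenic regions (the
  partition constraint covers TSS/TES/gene body only), so a site may be
  counted in both classes.

All coordinates are clipped to `[0, chromosome length)`.

## Tag-ratio levels and the zero-count guard

5mC = BGT/HpaII and 5hmC = MspI/BGT per site. A fully methylated site has
zero HpaII tags, making the raw ratio undefined exactly where the signal is
strongest; the denominator is therefore floored at ε = 1 normalized tag
(configurable). Sites with a zero numerator carry no signal for that
context and are not emitted. Ratios are not capped. Optional quantile
normalization (per library, across samples) replaces each sample's sorted
values with the across-sample mean at the same quantile; unequal sample
depths are interpolated onto a common quantile grid.

## MR search

Adjacency mode scans each region's sites in coordinate order and breaks a
cluster when the gap to the previous site exceeds `a` (default 2000 bp;
gaps exactly `a` are allowed). Clusters below the per-class minimum count
are discarded: `mc1` (default 3) for TSS/TES, `mc2` (default 5) for gene
body/5′ distance/intergenic, `mc3` (default 3) bound to enhancer/custom
regions — the binding of the third knob to user regions is this package's
choice and can be re-bound by constructing `MrSearchParams` directly.
Region membership is half-open (`start ≤ pos < end`); a site inside two
overlapping regions contributes to both independently. Window mode tiles
each region from its own start into `window_size` bins (region-anchored
tiling, not genome-anchored); the same count minimums apply.

## Pairing and imputation

MRs from the two conditions are paired when their bounding intervals
overlap by ≥1 bp within the same chromosome, region class and gene
linkage; transitively overlapping MRs merge into one locus (many-to-many
overlaps collapse rather than multiply). The paired site grid is the union
of positions. Missing entries are imputed by zeros (default — a missing
site plausibly is a truly unmethylated state, and discarding it would drop
exactly the informative loci), by the condition's MR median, or by the
nearest observed position's level. Replicates within a condition are
pooled; levels observed at the same position are averaged so vectors stay
aligned one-to-one with positions. Unpaired MRs are dropped and counted in
the log.

## Testing

The default test is the Wilcoxon rank-sum with the hybrid rule: exact
enumeration when `nx < 10` (nx = number of aligned sites), otherwise the
two-sided normal approximation of the Mann–Whitney U with tie correction
(scipy). An alternative small-sample gate, `min(nx,ny) < 10 and
nx + ny < 20`, is available behind `mranksum_rule=True` but is not the
default.

The exact path computes the null distribution of the rank-sum of the case
group over all C(nx+ny, nx) equally likely assignments of the pooled
mid-ranks. Mid-ranks are half-integers, so they are scaled by 2 to exact
integers and the distribution is built by a subset-sum generating-function
(“shift”) DP in integer arithmetic — polynomially, but numerically
identical to literally listing every assignment (the test suite verifies
this against a listing oracle). The two-sided *P*-value is twice the
smaller tail probability of the observed statistic, capped at 1, matching
the convention of the approximation it hands over to. Probabilities are
exact rationals (`Fraction`) until the final float conversion.

Degenerate cases: identical case/control vectors give p = 1 under every
test; a zero-pooled-variance *t*-test gives p = 1 for identical constants
(and p = 0 for distinct constants, which cannot arise from identical
vectors). With `isST = 1`, a pair is admissible only when each condition's
observed levels are same-trend — all nonzero consecutive differences share
one sign; zero differences veto nothing, and the check precedes testing
(inadmissible pairs are skipped and counted), since the trend condition
reads as MR admissibility, not post-hoc filtering.

BH correction, when enabled, is applied over all records of one context
globally (not per region class) and the α threshold then applies to the
adjusted values. Direction comes from rratio computed on original
(non-imputed) levels only; rratio = 0 (including the 0/0 case) maps to
direction "none".

## Summaries

* Relative density: sites with level strictly above the threshold (1.0 for
  tag ratios, 0.5 for fractions) per Mb of the class's merged,
  non-redundant length. The per-Mb unit is this package's normalization
  choice and is labelled in the output metadata.
* Direction percentages: hyper/(hyper+hypo) per class; classes without
  DMRs are absent rather than zero.
* Metagene profile: each gene's TSS/body/TES sub-intervals are rescaled to
  unit length (100 bins each by default) on a common axis, flipped for '−'
  genes so the axis runs TSS→TES; within a gene every bin takes the level
  of the nearest observed site; the profile is the per-bin mean over genes
  with ≥1 site (siteless genes are excluded from the denominator).
  Smoothing = centred moving average (window 3 bins; even windows are
  widened by one to stay centred; reflective padding, chosen because the
  moving-average formula itself has no boundary treatment) followed by a
  1-D Gaussian filter (σ = 2 bins, reflective). Both kernels are
  normalized, so constants are preserved and the operation is linear.
* Every figure is exported together with a TSV of exactly the plotted
  values, so all plots are regenerable from text outputs.

## Pipeline and determinism

Eight stages (qc, annotate-genome, preprocess, find-mrs, prepare-dmr,
dmr-search, annotate-dmrs, summarize) write under one run directory and
record completion markers, keyed by a hash of the configuration and input
digests, in `manifest.json`; re-running with unchanged inputs is a no-op
and running a stage early raises an error naming the missing prerequisite.
MR search, pairing and testing shard by chromosome across `-p` worker
processes; results are canonically sorted before writing, so outputs are
byte-identical for any CPU count. The statistical stages are fully
deterministic; randomness exists only in the fixture generator, seeded and
recorded in the manifest.

## Synthetic data generator

`generate_fixtures` emulates a two-condition experiment: a multi-chromosome
genome with genes every 30 kb (6 kb long, random strand), one cluster of
5–8 CpG sites (150 bp spacing) at each promoter, per-site levels drawn
i.i.d. Gaussian around a baseline (0.5 fraction for WGBS, clipped to
[0, 1]; tag ratio 1.2 for HMST, floored at 0.05) with dispersion 0.1. A
chosen fraction of loci (10% by default) receives a shift of ±0.35 — 3.5×
the noise scale — in the case condition; `missing_rate` (default 0)
independently drops sites from one condition to exercise imputation. HMST
tag counts are built by inverting the ratio definitions at fixed HpaII
depth 20, with an independent null series for the 5hmC context. The truth
table of planted loci supports parameter-recovery measurement
(`dmrkit.benchmark`).

What the generator does *not* emulate: spatial autocorrelation of
methylation along a region, coverage-dependent sampling noise
(beta-binomial counts), CpG-density variation, batch effects, or
biologically structured missingness. Passing recovery/type-I checks on
these fixtures therefore validates the statistical machinery under the
stated noise model, not performance on any real data set. Default problem
sizes (2000 loci for the calibration runs, 80–300 genes in example runs)
were chosen so the whole analysis runs in seconds on one CPU while keeping
binomial error on measured fractions below ~0.5 percentage points.

## Known limitations

* One test per paired locus; no spatial smoothing or HMM segmentation of
  levels within regions.
* Coverage is used only for QC (fraction of sites ≥15×), never as a test
  weight.
* The gene-annotation step is transcript-naive: overlapping transcripts
  generate overlapping regions, and a locus may be tested once per
  transcript-linked region (deduplication removes only identical regions).
* rratio is undefined (reported 0, "none") when both condition medians are
  exactly 0, which can occur under zeros imputation with a fully missing
  side — such pairs cannot form, but constructed inputs can reach it.
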