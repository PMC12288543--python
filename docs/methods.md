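# Methods

`plastcov` quantifies the depth and evenness of sequencing coverage in
quadripartite plastid (chloroplast) genomes and runs the statistical battery
that relates those quantities to genome structure, assembly quality, and
methodological provenance.  This note records the models, the parameter
choices, the numerical conventions, and what the synthetic cohort does and
does not establish.

## Data model

A plastome is a circular molecule partitioned into a large single-copy region
(LSC), a small single-copy region (SSC), and two inverted repeats (IRb, IRa)
that are reverse complements of one another.  Internal coordinates are
1-based inclusive (the GenBank convention); BED and bedGraph inputs are
converted at the boundary.  An interval whose end precedes its start wraps
the numeric origin; all length arithmetic is circular, and the four
partitions must cover every position exactly once.

## Coverage metrics

**Windows.** Per-base depths are summarized in fixed windows (default 250 bp)
tiled independently within each partition from its 5' boundary, so windows
never straddle a partition junction; a trailing partial window is kept and
weighted equally.  The window statistic is the arithmetic mean of per-base
depths (a median variant is available).  The plastome-wide summary is the
mean and the sample (n−1) standard deviation across *all* windows, both IR
copies included — upstream mapping is assumed to place each read at a single
best position, so the IRs carry independent evidence.

**WRSD.** A window with reduced sequencing depth is one whose mean depth is
*strictly* below (plastome mean − 1 sd) of window depths.  Strictness matters
only in the degenerate constant-coverage case (sd = 0), where a non-strict
rule would flag every window.  Counts are reported per partition and per
coding status (a window is coding iff strictly more than 50 % of its bases
overlap the union of gene spans, introns included, strand-agnostic) and
normalized per 1,000 bp of cumulative category length.

**E-score.** With `D` the multiset of per-base depths,
`C = round_half_even(mean(D))` and `D2 = {d in D : d <= C}`:

    E = 1 − (|D2| − Σ(D2)/C) / |D|

the complement of the fraction of reads that would need redistribution from
above-average to below-average sections to even out coverage; `E ∈ [0, 1]`,
reported to three decimals.  The rounding convention for `C` is isolated in
one function.  Two numerical caveats established during development: (i) for
Poisson(λ) depth with `C = λ` the score is exactly `1 − P(X = λ)` (≈ 0.960 at
λ = 100), so even perfect Poisson coverage does not reach 1; (ii) appending
zero-coverage positions is monotonically degrading at a *fixed* reference
`C`, but the rerounding of `C` can lift the reported score by up to ~0.05 at
low depth — `e_score(profile, reference_coverage=...)` exists to compare
profiles at a common reference.

**Outlier screening.** Tukey far-out fences (quartile ± 3×IQR, type-7 linear
interpolation quartiles).  WRSD variables are screened two-sided; the
E-score uses only the lower fence (evenness fails low, not high).  Screened
samples are excluded from tests but retained in descriptive tables.

## Assembly quality

Two sequence-derived metrics: the count of IUPAC-ambiguous characters
(anything outside A/C/G/T), and the nucleotide mismatches between IRa and the
reverse complement of IRb — Hamming distance at equal lengths, unit-cost
banded Levenshtein distance otherwise (indels cost 1; the band starts at the
length difference and doubles until the distance fits, so near-identical IRs
cost O(n·d)).  The mismatch count is computed only after a synteny check
(equal gene content and mirrored gene order across the IRs); failures yield
NA and propagate pairwise, not listwise.

Cohort standardization uses Tukey's ladder of powers: after a +1 shift (both
metrics are zero-inflated, medians 0), the exponent
λ ∈ {−2, −1, −1/2, 0 (log), 1/3, 1/2, 1, 2} maximizing the Shapiro–Wilk W of
the transformed values is chosen, values are min–max scaled and flipped so 1
means high quality.  Degenerate inputs: an all-zero vector maps to all 1.0
(nothing wrong anywhere); any other constant maps to 0.5 with a warning.

## IR boundary polishing

Archived IR annotations are frequently off by tens of bases.  The
reverse-complement pairing maps IRb position `p` to IRa position `S − p`
(circularly) for a fixed register `S`.  The two annotated junctions each
propose a register (outer: IRb start + IRa end; inner: IRb end + IRa start);
the better-scoring register over the annotated span is adopted, after which
each junction is contracted past mismatching terminal pairs and extended
while flanking bases pair exactly, the partner boundary following through
the register.  This recovers asymmetric truncations (the common archival
error) and guarantees equal corrected IR lengths; LSC/SSC are re-derived as
the complementary arcs.  Genomes whose annotated IRs are wholly dissimilar
(mismatch fraction > 0.5 under both registers and no ≥ 3 bp exact extension
at either junction — the 3 bp floor keeps a 1-in-4 chance base match from
counting as "extension") are left untouched with an `IR-unpolishable`
warning; the polisher never invents annotations where none exist.  The
procedure is idempotent.

## Univariate statistics

Non-parametric throughout: tie-corrected Kruskal–Wallis (≥ 3 groups; p from
χ² with k−1 df) with effect size η² = (H − k + 1)/(n − k), which may be
negative; Wilcoxon rank-sum via the normal approximation with tie-corrected
variance and 0.5 continuity correction (the data contain ties), paired with
classic pooled-SD Cohen's d reported as a magnitude; Spearman's rank
correlation with the t approximation at n−2 df; mean-centered Levene's test
for homoscedasticity.  Pairwise Wilcoxon p-values are Benjamini–Hochberg
adjusted over the full pair family of one variable; the single coding/
non-coding comparison is unadjusted.  Labels: p < 0.05/0.01/0.001 =
\*/\*\*/\*\*\*; effects small/moderate/large at η² ≥ 0.01/0.06/0.14,
|d| ≥ 0.2/0.5/0.8, |R_s| ≥ 0.1/0.3/0.5 (half-open ≥ bins).  Categorical
states with fewer than five members are reassigned to the explicit `missing`
state, which is excluded from tests; at least two states must survive.

## Multivariate models

Ordinary least squares with treatment coding (reference levels fixed at the
canonical orders LSC/IRb/SSC/IRa, coding/noncoding, alphabetical platforms)
reporting the adjusted R²; and CART regression trees (squared-error loss,
min leaf 7, max depth 5) with cost-complexity pruning selected by seeded
10-fold cross-validated RMSE.  Categorical predictors are one-hot encoded —
a binary level-vs-rest split per node rather than arbitrary level subsets —
and per-variable importance sums the SSE reduction over a variable's
dummies, rescaled so the maximum is 100.  "Percent variation explained" for
trees is the training R² after pruning; the CV RMSE is reported alongside.
Assembly software never enters multivariate models: its missingness
dominates, and the `missing` level would be the most influential category.

The depth models use sample × partition × coding-status cells (WRSD count
per cell, normalized per kb of cell length) so both categorical predictors
are defined on every row; covariates are partition length and average read
length.  The evenness models are per-sample (E-score on platform and the
two quality scores; covariates genome length and average read length).
Confounding is probed by fitting each model with and without covariates: if
a covariate carries the signal, its inclusion demotes the categorical
predictor's importance (tree) and |t| (linear).  In the test harness for
this property, partition length varies within partitions with cv 0.3; with
near-collinear lengths the factor is a coarsened copy of the covariate and
the question is unidentifiable.

## Phylogenetic signal

Moran's I uses row-normalized inverse patristic-distance weights with null
expectation −1/(n−1) and a two-tailed permutation p on |I − E[I]|.
Blomberg's statistics divide the observed MSE0/MSE ratio by its
Brownian-motion expectation computed from the phylogenetic covariance C
(root-to-MRCA shared path): K centers MSE0 on the ordinary mean with
expectation [tr(C) − 1'C1/n]/(n−1); K* centers on the GLS ancestral estimate
â = (1'C⁻¹x)/(1'C⁻¹1) with expectation [tr(C) − n/(1'C⁻¹1)]/(n−1); MSE is
the GLS mean squared error (x−â)'C⁻¹(x−â)/(n−1) in both.  Both equal 1 under
Brownian motion; permutation p-values are upper-tailed (999 permutations,
p = (r+1)/1000), since signal inflates both.  Missing tips are pruned per
trait.

Correlograms compute Moran's I per patristic-distance class (30 equal-width
classes over (0, max], binary within-class weights); classes with fewer than
10 unordered pairs are NA.  95 % CIs come from a percentile bootstrap over
tips with replacement (100 resamples; duplicate pairs have distance 0 and
fall outside every class); a class is flagged +/− when its CI excludes
−1/(n−1).  Class count and bootstrap size are configuration keys, as is the
tips-versus-pairs resampling choice (tips is the default).

Every trait is contextualized by three distributions: empirical; randomized
(values permuted across the same non-missing tips — mean, dispersion, and
missingness exactly retained); and enforced Brownian motion (simulated along
the tree, affinely rescaled to the empirical mean/SD, empirical missing
pattern re-imposed).  A trustworthy testing setup shows signal only under
the enforced distribution.

## Synthetic cohort

The generator emulates an archived plastome cohort, not library chemistry:

* **Genomes.** Canonical partition lengths LSC 85,000 / IRb 25,500 /
  SSC 18,000 / IRa 25,500 bp (≈154 kb), GC 0.37, ~70 single-copy genes plus
  8 genes mirrored into both IRs (synteny true by construction).  IRa is the
  exact reverse complement of IRb before any requested perturbation; the
  single-copy bases flanking each IR junction are mutated so they never
  chance-pair, making the annotated boundaries exactly the maximal repeat —
  an injected truth for the polisher.  Ambiguities are injected into
  single-copy regions only, so both quality metrics remain exact truths.
  Per-genome indel perturbations use a single indel type so the length
  difference equals the indel count.
* **Coverage.** Per-base negative-binomial depth (mean 100×, size 30 —
  giving the counting-noise evenness of a good short-read library), an
  optional unimodal GC-bias multiplier centered at GC 0.4, and Poisson-placed
  250 bp low-coverage dips (depth × 0.2 inside a dip).
* **Cohort structure.** Platforms act on evenness *only* through their mean
  dip rate (0.05–0.35 dips/kb), never through mean depth; per-sample dip
  rates are Gamma-distributed around the platform mean (shape 2) and
  per-sample dispersion is lognormal (σ 0.5), because archived cohorts mix
  libraries and protocols.  These values were calibrated once against the
  published cohort anchors (cohort E-score mean ≈ 0.90 with IQR ≈ 0.90–0.95,
  platform means spanning ~0.85–0.91 with within-platform SDs of 0.02–0.05)
  and then frozen.  Assembly defects are zero-inflated (both metric medians
  are 0).  Partition lengths vary across samples (cv 0.05, IRs equal within
  a genome); software labels are assigned independently of everything — the
  null the analysis should confirm.
* **Trees and traits.** Yule trees simulated forward in time (waiting times
  exponential in the lineage count, a final no-split epoch so no terminal
  branch is zero) and rescaled to unit depth; traits are Brownian (σ² = 1
  from root 0) or white noise.

A green test on this cohort establishes that the estimators, tests, and
calibrations behave correctly under the stated generative model.  It does
not establish anything about real mapping artifacts (repeat-boundary
effects, tie-breaking), real GC chemistry, annotation errors beyond boundary
shifts, or heteroplasmy — none of which the generator models.

## Known limitations

* The IR mismatch count for unequal-length IRs is a unit-cost edit distance;
  aligner-based mismatch counts from other tools may differ for the same
  genome, especially for pathological assemblies (e.g. tandem-duplicated
  IRs).
* Tree level-subset splits on categoricals are approximated by one-hot
  splits (see the multivariate section).
* The Kruskal–Wallis power of the design "one of six groups of n = 20
  shifted by one pooled SD" is ~0.85 at α = 0.05 (noncentrality ≈ 16.7 on
  χ²₅); a power requirement of 0.9 is not attainable under that exact
  design.
* Permutation p-values have resolution 1/1000 at the default 999
  permutations.
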