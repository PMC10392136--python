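# Methods

`bcproteodyn` reimplements the computational analyses of a DIA-proteomic
study of a breast-cancer cell-line panel as a tested pipeline: matrix QC,
protein-complex co-expression, TNBC differential expression, nested
cross-validated elastic-net drug-response prediction, and drug-perturbation
time-course analysis.  A synthetic-data generator with planted ground truth
stands in for the deposited datasets, so every stage is scored against a
known answer.

## Data model

All quantitative layers are log2 abundances in a features x samples matrix
with explicit missing values (`NaN` internally, `NA` on disk); the mutation
layer is binary and complete.  Sample identity (cell line, replicate group,
batch) lives only in the sample annotation, so replicate-level (4 columns
per line) and cell-line-averaged matrices flow through the same code.  A
`RunConfig` collects every threshold; a run is fully determined by
(inputs, config, seed).

## Quality control

* **Missing-rate filter** — a feature is removed when its missing fraction
  strictly exceeds 0.9 ("over 90 %"), so a feature at exactly the threshold
  is retained.
* **Outlier samples** — flagged by a robust z-score (median/MAD, consistency
  constant 1.4826) on per-sample identification counts, threshold 3.  The
  count criterion replaces a visual PCA call; the threshold is configurable.
* **Replicate correlations** — pairwise-complete Pearson r between all
  sample pairs, labeled technical (groups 3 vs 4 of one line), biological
  (two of groups 1–3), else non-replicate.  Pairwise-complete observations
  are used everywhere: with ~35 % missingness, listwise deletion would
  discard most features.
* **CV by abundance** — per feature and line, sd/mean of linear-scale
  replicate intensities (>= 2 observed), averaged over lines, binned into
  abundance quantile bins.
* **Batch correction** — per-feature batch mean-centering (subtract batch
  mean, restore grand mean).  This is a location-only adjustment: it removes
  additive instrument offsets exactly and leaves within-batch variance and
  the missingness pattern untouched.  It preserves each feature's grand mean
  to numerical precision.
* **Replicate averaging** — mean of observed replicate values per line;
  missing only where all replicates are missing.

## Complex co-expression

Every unordered pair of complex subunits quantified in the cell-line-
averaged matrix contributes a Pearson correlation across lines (minimum 3
co-observed lines; zero-variance members dropped with a recorded reason).
Protein-level and transcript-level pair correlations are compared with a
two-tailed unpaired equal-variance t test on the raw r values — no Fisher-z
transform, matching the source analysis; statistically debatable, fidelity
wins.  Top pairs are ranked by r with deterministic lexicographic
tie-breaks.

## Differential expression

Per feature: two-tailed unpaired Student's t test on log2 values (equal
variance by default, Welch behind a config flag), fold change from the
difference of log2 group means (a geometric-mean ratio — consistent with the
log2 matrix and volcano conventions), Benjamini–Hochberg adjustment across
tested features only, and the joint call adjusted p < 0.05 with FC > 1.5 or
< 0.67.  Features with fewer than two observed values in either group are
reported untested and excluded from the B-H family.  Degenerate
zero-variance features get p = 1 when group means agree and p = 0 when they
differ.  The signature is the n most significant differential proteins
(smallest adjusted p, ties by larger |log2 FC|, then feature id — the
ranking rule is this package's choice since the source states none), and its
quality is summarised as the mean silhouette of the group labels under
correlation distance over complete-case signature features.

## Drug-response prediction

The response is log10 IC50 per (cell line, drug).  Design matrices are
assembled from any combination of layers (mutation / protein / transcript /
RPPA); intensity layers are imputed first with a feature-neighbour kNN rule
(the k nearest features by mean-squared difference over co-observed samples,
observed in the target sample, supply their mean; k = 10).  Mean squared
difference rather than raw Euclidean distance corrects for unequal overlap
between feature pairs.

The penalised objective is the standard elastic net

    (1/2n)·Σ(yᵢ − β₀ − xᵢβ)² + λ·( α·‖β‖₁ + (1−α)/2·‖β‖₂² )

solved by scikit-learn coordinate descent.  The nested procedure per drug:

1. **Tuning** — grid over α (0.1–1.0) x a geometric λ path from the critical
   λ of the training data down by a factor 100; CV MSE averaged over
   replicated k-fold partitions; ties prefer larger λ, then larger α (the
   sparser model).  The λ-path shape (length, span) is unstated in the
   source; a standard geometric path is used and recorded in config.
2. **Bootstrap averaging** — the tuned model refit on random 90 % subsamples
   of the lines *without* replacement ("a random subset of 90 % of the
   available cell lines" describes subsampling, not resampling);
   coefficients averaged; predictors ranked by |mean coefficient|, ties by
   feature index.
3. **Top-k selection** — OLS on the top-k predictors scored by 10-fold CV
   over one common fold partition for all k; k is the smallest value whose
   CV error is within one standard error of the minimum (1-SE rule).
4. **Outer evaluation** — leave-one-out over cell lines; steps 1–3 re-run
   per fold on the remaining lines only, standardisation parameters
   included, so the held-out prediction never sees the held-out line.
   Predictive power is the Pearson r between observed and LOO-predicted
   responses.  Drugs with fewer than 10 observed responses are marked
   invalid.  Intensity features are standardised on training lines (computed
   once per outer fold, before the bootstrap loop); mutation features stay
   binary.

Two presets share one code path: `paper` (α step 0.1, 10x10-fold inner CV,
200 bootstraps, k_max 100) and `fast` (α ∈ {0.1, 0.5, 1.0}, 12-point λ path,
3x5-fold inner CV, 50 bootstraps, k_max 50, solver tol 1e-3) for desk-scale
runs and tests.

A property worth knowing: because the predictor ranking is computed on the
full training set (as in the source pipeline), the k-selection CV inherits
selection bias, and the 1-SE k tends to exceed the true support size even at
low noise, while still *containing* the true predictors.  The outer LOO
estimate is unaffected — that is exactly what the outer loop is for.

## Perturbation dynamics

Profiles are replicate means per (protein, line, drug, time) over the six
sampling times {0, 4, 12, 24, 48, 72} h (a conflicting four-point listing in
the source's design overview is resolved in favour of the six-point
protocol).

* **IC50 screen** — per (drug, protein, time), Pearson r across lines
  between expression and log10 IC50 (pairwise-complete, >= 3 lines);
  proteins with computable r at all but at most one time point are averaged
  over computable times and classified resistance-associated (mean r > 0.7)
  or sensitivity-associated (mean r < −0.7).  IC50 enters on the log10 scale
  because it spans orders of magnitude; Pearson r is invariant to the linear
  rescaling this implies.
* **Fuzzy c-means** — in-package implementation of the standard alternating
  updates (memberships ∝ d^(−2/(m−1)), centroids u^m-weighted means) on
  z-scored profiles; fuzzifier m = 2, c = 6 by default (neither is stated in
  the source; clustering is a grouping aid — the selection below is the
  operative filter, so the headline selection does not depend on c).
* **Trend statistics** — one-way ANOVA of log2 replicate values across time
  points; last-vs-first fold change 2^(mean₇₂ − mean₀); a direction call
  (+1/−1) only where the mean profile is monotone-consistent (Spearman |ρ|
  vs time >= 0.8, configurable).  B-H adjustment is applied within each
  (line, drug) family.
* **Opposite dynamics** — a (protein, line, drug) call is *qualified* when
  adjusted ANOVA p < 0.05, |fold change| > 2 and the monotone gate passes.
  Per drug, a protein is selected when a strict majority of TNBC lines share
  a qualified direction and a strict majority of non-TNBC lines share the
  opposite one; the final set is the union over drugs (per-drug panels in
  the source suggest union; `intersect_drugs` implements the strict
  all-drugs reading).  Note a structural property of small panels: with 5+4
  lines, any relabeling of lines other than the maximally mixed one leaves
  both groups with a true-direction majority, so label-shuffle nulls must be
  restricted to maximally mixed relabelings to be informative.
* **Pathway consistency** — a pathway passes when at least ⌈3/5 · n_TNBC⌉
  TNBC lines and ⌈2/4 · n_non⌉ non-TNBC lines each carry a qualified call on
  at least one selected member (thresholds inclusive at the boundary).
* **PDPs** — per TNBC line, a 0 h vs 72 h differential call (t test, B-H
  within line, FC thresholds as above); persistently dysregulated proteins
  are those called in strictly more than 60 % of lines ("over 60 %").
  With 3 replicates and realistic dropout the per-line test has limited
  power (2-vs-2 comparisons are common), so the strict fraction rule
  recovers most but not all planted persistent shifts; transient responders
  (back to baseline by 72 h) are excluded by construction of the 0-vs-72
  comparison.

## Synthetic data

The generator's defaults are the study's design: 76 lines (39 TNBC), 6091
proteins, 29,140 transcripts, 123 mutations, 90 drugs, 34.7 % protein
missingness, median protein–mRNA r of 0.3, 3 biological + 1 technical
replicate per line with a group-4 batch offset; and 9 lines (5 TNBC) x 3
drugs x 6 times x 3 replicates at 33.6 % missingness for the perturbation
course.  Tests and the acceptance script run reduced feature counts
(hundreds to ~1000 proteins), which changes compute, not structure.

Mechanisms, and what they do and do not emulate:

* Transcripts are Gaussian per feature on log2 scale (baseline sd 2 gives
  the abundance dynamic range); protein j couples to transcript j with a
  per-feature loading solved so the protein–mRNA correlation equals the
  target for complex members too (their shared factor otherwise dilutes it).
* One latent factor per complex, loading 1 on all members — the simplest
  mechanism giving higher within-complex than random-pair correlation.
  Complexes are disjoint; real complexes overlap.
* Drug response is a sparse linear function of 5 standardized planted
  protein values (β = ±1) plus Gaussian noise (sd 0.5), shifted to a log10
  IC50-like scale.
* Cohort missingness is logistic in the instantaneous log2 abundance
  (missing-not-at-random; intensity-dependent drop-out), with the intercept
  solved by bisection to hit the target rate within ±0.02.  Time-course
  missingness is logistic in the protein's *baseline* abundance instead:
  DIA detectability tracks a protein's peptide properties more than its
  modest within-course changes, and instantaneous-abundance drop-out would
  systematically erase the 72 h point of every down-regulated protein.
* Planted time-course signals (monotone ramps reaching baseline x FC at
  72 h, an opposite-direction set flipped between TNBC and non-TNBC lines,
  transient responders, IC50-tracking offsets with a slope solved for the
  target cross-line correlation) are drawn from the upper 60 % of baseline
  abundance — any protein *selected* in a real experiment is necessarily
  well quantified.  IC50-tracking proteins carry no random line offset so
  the noiseless construction gives r = 1 exactly.
* Replicate structure: biological noise sd 0.25, technical sd 0.10, batch
  offset 0.3 (log2).  These satisfy the qualitative QC expectations
  (technical r > biological r > non-replicate r; replicate CV < 0.2).  A
  homoscedastic Gaussian model compresses replicate correlations toward 1
  relative to real DIA data, so the generated medians are higher than the
  published ones — the *ordering* is the tested property.
* Not emulated: peptide-level structure, retention-time effects,
  subtype-specific covariance beyond the planted shifts, overlapping
  complexes, batch effects beyond an additive offset.  Passing tests show
  the estimators recover the planted mechanisms under realistic dimensions
  and missingness; they do not certify performance on real acquisitions.

## Numerical choices

* Correlations need >= 3 co-observed values; degenerate (zero-variance)
  inputs are dropped with a recorded reason, never silently NaN.
* Fuzzy c-means stops when the objective decreases by < 1e-6; memberships
  at an exactly coincident centroid are set to the indicator of that
  centroid.
* The elastic-net solver tolerance is 1e-4 (`paper`) / 1e-3 (`fast`);
  closed-form contract tests run it at 1e-10.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical (inputs, config, seed) reproduce
  byte-identical outputs.

## Known limitations

* The location-only batch adjustment does not touch scale or covariance
  batch effects.
* The t test on raw correlation values (not Fisher z) and the equal-variance
  default mirror the source at the cost of statistical orthodoxy; both are
  switchable.
* PDP detection compares only 0 h vs 72 h; a multi-time-point persistence
  definition would be stricter.
* With 9-line panels, opposite-dynamics selection is inherently robust to
  most label relabelings (see above) — a larger panel would be needed for a
  conventional permutation null.
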