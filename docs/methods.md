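# Methods

## The generative model behind the synthetic cohorts

Every stage of the pipeline is exercised against cohorts drawn from an
explicit latent model, so recovery can be checked against ground truth.
For sample *s*, miRNA *m*, on RT batch (plate) *p*:

    log2 copies(s, m) = baseline(m) + class_effect(s, m) + gamma(p, m)
                        + eps(s, m),
    eps ~ N(0, [sigma(m) * delta(p, m)]^2)

* `baseline(m) ~ U(6, 14)` log₂ copies — the dynamic range a multiplexed
  qPCR panel spans.
* `class_effect`: for each of the five diagnostic classes,
  `n_markers_per_class` miRNAs (default 12, half up / half down) are
  shifted by ±`effect_size` (default 1.5 log₂ units) in samples of that
  class. These are the planted one-vs-rest markers recorded in
  `GroundTruth.true_markers`.
* `gamma(p, m) ~ N(0, batch_shift_sd)` (default 0.4) and
  `delta(p, m) = exp(N(0, batch_scale_sd))` (default 0.1): additive and
  multiplicative per-batch effects per miRNA — exactly the location/scale
  model the empirical-Bayes batch correction assumes, so correction
  recovery is well-posed. One RT batch per cohort × collection site
  (discovery: NUH only; validation: NUH/TTSH/UMMC).
* `sigma(m) ~ U(0.5, 1.5) * biological_sd` (default 0.6 log₂ units)
  inter-patient variability. The value is a deliberate choice: large
  enough that t-tests are non-trivial, small enough that an effect of 1.5
  log₂ units is a strong marker, in line with the compressed dynamic
  range of FFPE-derived RNA.

The read-out maps latent copies to threshold cycles through a
perfect-efficiency curve, `Ct = intercept(m) − log2(copies)`, with
`intercept(m) = 40 + N(0, 0.3)` (Ct at one copy), then adds a per-sample
workflow shift `w(s) ~ N(0, spike_in_sd = 0.3)` cycles — shared by that
sample's spike-in wells, which is what makes it correctable — and
per-well duplicate noise `N(0, replicate_sd = 0.15)` cycles. A slope of
−log₂10 ≈ −3.32 cycles/decade corresponds to amplification efficiency
1.0, making the inverse mapping analytically checkable. Any well whose Ct
reaches the no-template-control level (`ntc_ct = 38`) is emitted at
exactly that level: undetected.

Structural features emitted per the assay design: technical duplicate
sample wells; three spike-in wells per sample (base Ct 21/24/27); per
plate, a six-point 10-fold standard series per miRNA (10¹–10⁶ copies) and
two NTC wells. A `dropout_fraction` of miRNAs (default 0.13, so ~313 of
360 survive at the default sizes) is forced undetected in 15–80% of each
cohort's samples, guaranteeing they fail the >10% detection filter; the
real per-miRNA dropout pattern of such assays is unknown, so the fraction
is an explicit free parameter rather than an assertion.

Cohort sizes and tissue sites default to the recruited design: discovery
n=100 (SLL 23, FL 21, MCL 20, MZL 19, RL 17, all one site), validation
n=282 (20/74/22/74/92, three sites), with nodal/extranodal proportions
per class scaled from the recruitment table (e.g. MZL fully extranodal).
Tissue site influences no expression value; it exists as the covariate
the batch correction must protect and as a classifier feature.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: amplification chemistry (primer efficiency
differences beyond intercept jitter, preamplification bias), FFPE
degradation kinetics, class-dependent dropout, correlated miRNA modules
(co-regulation), label noise in the reference diagnosis, and site
differences beyond location/scale effects. Synthetic cohorts at the
planted effect size are close to separable, so classifier accuracies here
are upper bounds, not estimates of clinical performance.

## Quantification conventions

* Technical duplicates are averaged on the Ct scale (the measurement
  scale, and the qPCR convention); a pair with one detectable member uses
  that member; duplicate pairs of detectable wells more than 1.0 cycle
  apart are flagged in a QC table but still averaged.
* Detectability is judged against the *minimum* NTC Ct on the well's
  plate — the strictest reading of "higher than the NTCs" when two NTCs
  are present. An NTC that never amplified enters as Ct 40.
* Undetected entries are imputed at the plate's detection limit (the copy
  number interpolated at the minimum NTC Ct) and flagged False in the
  mask; the detection filter removes pervasively missing miRNAs before
  any statistics, so the imputation only backstops sporadic dropouts.
* Spike-in correction shifts each sample's detectable sample-well Cts by
  the deviation of its mean spike-in Ct from the cohort median of those
  means. Undetected sentinel values are not shifted (they are not
  measurements, and shifting them would flip detectability calls).
  Spike-in wells are retained unchanged for audit; the corrected PlateSet
  carries a flag making a second application a no-op.
* Standard curves are fit per miRNA by least squares, pooling each
  miRNA's standard wells across plates; fits with r² < 0.95 are visible
  in the curve QC table rather than rejected.

## Normalization and batch correction

The discovery workflow is: detection filter (undetected fraction ≤ 0.10
retained — the boundary is inclusive) → global-mean normalization (each
sample centred on its mean log₂ expression over retained miRNAs) →
per-miRNA Z-scoring (ddof=1). The validation cohort, profiled on the
100-miRNA panel only, is normalized by the mean of the 10 housekeeping
miRNAs; the detection filter is a discovery-stage decision and is not
re-applied there.

`combat_correct` is the parametric empirical-Bayes location/scale
adjustment: per-miRNA standardization under an OLS model containing batch
indicators and protected covariates (categorical covariates dummy-coded,
drop-first), per-batch per-miRNA location (γ̂) and scale (δ̂²) estimates,
shrinkage across miRNAs with a normal prior on γ and an inverse-gamma
prior on δ² (moment-matched hyperparameters, coupled posterior updates
iterated to 1e-8), adjustment, and back-transformation. A single batch
returns the input unchanged; singleton batches and designs in which a
covariate is confounded with batch are rejected. The residual per-miRNA
between-batch offset after correction is the EB-shrunken sampling noise
of the batch means — of order (δ/n_b)/sd(γ̂) — which is why recovery
checks assert on site means averaged across null miRNAs.

`merge_cohorts` runs housekeeping normalization per cohort, corrects the
validation cohort across its three sites, then corrects the cohort pair
(site-level first, mirroring the order in which the two corrections are
described), always protecting tissue site and diagnosis, and appends the
numeric tissue indicator (nodal=0, extranodal=1). Whether to re-Z-score
the merged matrix before classification is exposed as
`PipelineConfig.zscore_merged`, default off: the merged values are
already housekeeping-anchored, and re-scaling would discard
between-cohort comparability the housekeeping step just established.

## Panel construction

Student's t-tests (equal-variance form, as the named test; a Welch flag
exists) per miRNA for 5 one-vs-rest and 10 one-vs-one contrasts, on the
globally normalized Z-scored discovery values. Per contrast, the 3
smallest-p up-regulated and 3 smallest-p down-regulated miRNAs are
selected; ties break by larger |t|, then lexicographic id. The panel is a
set: a candidate already selected by an earlier contrast is skipped and
the next-best substitutes, keeping tier counts exact (30 + 60); the
one-vs-rest tier is filled before the one-vs-one tier. One-vs-one pairs
are ordered alphabetically and "up" means higher in the first class.
Housekeeping miRNAs are the 10 lowest variances outside the marker tiers.
No multiple-testing correction enters selection — it is a pure ranking,
and the cross-cohort sign-concordance check (strict sign match; a zero
difference never validates) is the guard against noise markers.

## Classification

Features are the 90 candidate markers plus the tissue indicator. The
harness is `n_iterations` (default 100; tests and the acceptance script
use 20, and 5 for the feature-count curve — cohort-scale choices that
keep the full suite fast while the repeated-CV averaging still
stabilizes the estimates) × stratified 4-fold outer CV; per outer
training split an inner stratified 3-fold grid search tunes the SVM cost
over integers 1–10; the tuned radial-kernel model (kernel scale
1/(n_features·Var(X)), the standard heuristic, so only cost is tuned;
one-vs-one voting for the 4-way task) predicts the held-out fold.
Held-out predictions pool into a predicted×actual confusion matrix whose
column sums are conserved (n_samples × iterations); accuracy is reported
both pooled (headline) and as the mean of per-iteration accuracies, since
either convention is defensible. For the binary screen, each iteration's
pooled decision scores give one ROC AUC; the summary is the mean with a
2.5/97.5 percentile interval over iterations. Feature ranking — needed
for the accuracy-vs-panel-size curve — uses the mean absolute t-statistic
across outer *training* folds (binary: the single contrast; multiclass:
the max over one-vs-rest contrasts); the ranking method for reduced
panels is not uniquely determined by the protocol being emulated, so this
documented, leakage-free statistic is the package's choice. The
permuted-label tests verify the harness leaks nothing: chance-level AUC
(0.5) and 4-way accuracy (0.25) within ±0.05, averaged over independent
permutations to remove the accidental signal any single permuted dataset
carries.

## Enrichment (miRSEA)

A miRNA "targets" a pathway if it has ≥1 strong-evidence target gene in
the set; pathways targeted by <10 or >500 miRNAs are excluded before
scoring. Targeting strength per (miRNA, pathway) is the upper-tail
hypergeometric probability of the observed target/pathway overlap within
the universe of all targeted genes. miRNAs rank by descending log₂ fold
change (lymphoma vs reactive, on normalized values). The running sum
advances by w/Σw at member positions — w = (|log₂FC| · −log₁₀ targeting
p)^α, α=1 by default and configurable; α=0 recovers the classical
unweighted KS statistic — and retreats by 1/(N−N_members) elsewhere; the
score is the signed maximum excursion, bounded by 1. The exact weighted
statistic of the original miRSEA formulation is not published in the
protocol being emulated; this multiplicative weight is the minimal
faithful combination of the two stated ingredients and is tested against
its own step-by-step oracle — equivalence with the original package is
not claimed.

Significance: miRNA identities are permuted over the ranked list
(default 10,000 permutations; 1,000 in the acceptance script) — fold-change
magnitudes stay at their rank positions while each pathway's
membership/targeting-strength columns are shuffled and weights
renormalized. p = (1 + #{same-sign null at least as extreme}) /
(1 + #{same-sign null}); normalizing within sign keeps null p-values
uniform, which the calibration tests check by KS. FDR follows the
pooled-null convention: for score s ≥ 0, q = [fraction of same-sign
pooled null ≥ s] / [fraction of observed ≥ s], mirrored for negative
scores, clipped to [0, 1], and made monotone by letting each pathway take
the minimum over itself and all less-extreme same-sign pathways.

## Reporting

PCA coordinates come from an eigendecomposition of the covariance of the
Z-scored candidate-marker matrix, with each component's largest-magnitude
loading forced positive (a deterministic sign convention, checked against
an independent decomposition to 1e-8). Heatmap ordering uses
average-linkage hierarchical clustering on Euclidean distances of the
same values. The two-stage diagnostic rule finalizes screen-negative
samples as reactive without a subtype call; screen-positive samples
receive a subtype from a model trained on the lymphoma samples.

## Determinism and degenerate inputs

All randomness flows from integer seeds through independent generator
streams (per-iteration fold seeds are derived as `seed + 1009·i` modulo
2³¹−1 and recorded in the CV report); identical config + seed reproduces
plates, panels, CV reports, and enrichment tables exactly. Degenerate
inputs fail loudly with the offending identifier: samples without
spike-ins, standard series with <2 distinct dilutions, zero-variance
miRNAs at Z-scoring, singleton or confounded batches, classes smaller
than the fold count, tied panel tiers sharing a miRNA, malformed GMT or
target-map lines (with line numbers). Zero-weight enrichment hits fall
back to equal steps rather than dividing by zero.

## Known limitations

* Synthetic separability: planted effects are additive and independent
  across miRNAs, so classifier metrics saturate near 1 at the default
  effect size; the pipeline measures recovery, not clinical accuracy.
* The ComBat variant is parametric only; no non-parametric fallback.
* Duplicate-discordance handling (flag + average) and the detection-limit
  imputation are conventions chosen here; alternatives (exclusion,
  NA-propagation) would change borderline entries.
* The enrichment weight and the feature-ranking statistic are documented
  package choices where the emulated protocol is silent; both are
  configurable and oracle-tested, but not claimed to match any external
  implementation.
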