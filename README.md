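# lymphomir

A tested, reusable implementation of a miRNA-expression diagnostic workflow
for small B-cell lymphomas, driven by a synthetic-cohort generator so every
stage can be validated against known ground truth.

## The problem

Distinguishing reactive lymphoid proliferation (RL) from the four common
small B-cell lymphoma subtypes — small lymphocytic lymphoma (SLL),
low-grade follicular lymphoma (FL), mantle cell lymphoma (MCL), and
marginal zone lymphoma (MZL) — is hard on morphology alone and normally
requires large immunohistochemistry panels and molecular testing. Tissue
miRNA expression profiles measured by multiplexed RT-qPCR on FFPE material
offer an objective, low-input adjunct. This package implements the full
analysis chain for such an assay, for bioinformaticians building or
evaluating qPCR-based diagnostic classifiers:

1. **Absolute quantification** (`lymphomir.quantify`) — spike-in
   correction of per-sample workflow variation, per-miRNA standard curves
   from six-point 10-fold dilution series (Ct = b + m·log₁₀ copies,
   efficiency = 10^(−1/m) − 1), no-template-control detectability calls,
   technical-duplicate averaging, interpolation to log₂ copy numbers.
2. **Normalization & batch correction** (`lymphomir.normalize`) —
   detection filter (miRNAs undetected in >10% of discovery samples
   removed), global-mean normalization, per-miRNA Z-scoring,
   housekeeping-set normalization, and parametric empirical-Bayes
   location/scale batch correction (ComBat) with collection site as batch
   and tissue site + diagnosis protected as covariates.
3. **Marker-panel design** (`lymphomir.panel`) — Student's t-tests for
   every one-vs-rest and one-vs-one contrast; the 3 most significant up-
   and down-regulated miRNAs per contrast (30 + 60 markers), plus the 10
   lowest-variance housekeeping miRNAs: a 100-miRNA panel with 90
   candidates, validated across cohorts by sign concordance of effects.
4. **Classification** (`lymphomir.classify`) — a radial-kernel SVM in
   repeated stratified 4-fold cross-validation with inner 3-fold tuning of
   the cost parameter over 1–10; a binary reactive-vs-lymphoma screen
   (ROC AUC with percentile CI) and a one-vs-one 4-way subtype model;
   algorithm comparison, t-statistic feature ranking, and
   accuracy-vs-panel-size curves.
5. **Pathway enrichment** (`lymphomir.enrich`) — miRNA set enrichment
   (miRSEA): hypergeometric targeting p-values against a strong-evidence
   miRNA→gene table, a weighted Kolmogorov–Smirnov-like running statistic
   over miRNAs ranked by fold change (hit weight |log₂FC| · −log₁₀ p),
   a 10–500 targeting-miRNA size filter, permutation p-values, and
   pooled-null FDR q-values.
6. **Synthetic cohorts** (`lymphomir.simulate`) — a generator emitting raw
   plates (duplicates, standards, NTCs, spike-ins) from a latent
   log₂-copy model with planted subtype markers, per-site batch effects,
   recruited tissue-site proportions, and engineered detection dropout,
   plus matching target-map/pathway resources with planted enrichment.

`lymphomir.pipeline.run_pipeline` chains everything, including the
two-stage diagnostic rule (subtype only what the screen calls lymphoma),
and writes a reproducible report bundle. Short narrative scripts for each
capability live in `examples/`.

## Worked example

```python
import lymphomir as lm

config = lm.SimulationConfig(
    n_mirnas=140,
    n_samples_discovery={c: 8 for c in lm.CLASSES},
    n_samples_validation={c: 14 for c in lm.CLASSES},
    n_markers_per_class=4, seed=4)
plates, annotation, truth = lm.simulate_cohort(config)
em, curve_qc = lm.quantify_plateset(plates)

disc = annotation.index[annotation["cohort"] == "discovery"]
filtered = lm.filter_detection(
    lm.ExpressionMatrix(em.values.loc[disc], em.mask.loc[disc]))
norm = lm.zscore_standardize(lm.global_mean_normalize(filtered.values))
panel, _ = lm.build_marker_panel(norm, annotation["diagnosis"])

panel_ids = [e.mirna_id for e in panel.entries]
val = annotation.index[annotation["cohort"] == "validation"]
merged = lm.merge_cohorts(em.values.loc[disc, panel_ids],
                          em.values.loc[val, panel_ids],
                          annotation, panel.housekeeping_ids)
X, y = lm.build_feature_table(merged, annotation, panel.candidate_ids,
                              "binary")
screen = lm.run_cv(X, y, "binary", n_iterations=10, seed=5)
print(panel.tier_counts())
print(f"screen accuracy {screen.accuracy:.1%}, AUC {screen.auc_mean:.3f}")
```

prints

```
{'ovr': 30, 'ovo': 60, 'housekeeping': 10}
screen accuracy 98.5%, AUC 0.999
```

The tier counts confirm the panel contract (30 one-vs-rest + 60
one-vs-one + 10 housekeeping = 100 unique miRNAs). The screen numbers are
pooled held-out performance over 10 repeats of stratified 4-fold CV on the
merged, batch-corrected cohort: with the generator's planted effect size
the classes are nearly separable, so accuracy and AUC sit close to 1 —
`examples/04_classify.py` shows the full confusion matrix and per-class
sensitivities, and `examples/05_feature_curve.py` how accuracy grows with
panel size.

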