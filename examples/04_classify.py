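"""Cross-validated diagnostic classification on a merged cohort.

Housekeeping normalization, two-stage batch correction (validation sites,
then cohorts), then the nested-CV radial-kernel SVM: the binary screen
(reactive vs lymphoma) and the 4-way subtype model.
"""

import lymphomir as lm

config = lm.SimulationConfig(
    n_mirnas=140,
    n_samples_discovery={c: 8 for c in lm.CLASSES},
    n_samples_validation={c: 14 for c in lm.CLASSES},
    n_markers_per_class=4,
    seed=4,
)
plates, annotation, _ = lm.simulate_cohort(config)
em, _ = lm.quantify_plateset(plates)

disc = annotation.index[annotation["cohort"] == "discovery"]
val = annotation.index[annotation["cohort"] == "validation"]
filtered = lm.filter_detection(
    lm.ExpressionMatrix(em.values.loc[disc], em.mask.loc[disc]))
norm = lm.zscore_standardize(lm.global_mean_normalize(filtered.values))
panel, _ = lm.build_marker_panel(norm, annotation["diagnosis"])

panel_ids = [e.mirna_id for e in panel.entries]
merged = lm.merge_cohorts(em.values.loc[disc, panel_ids],
                          em.values.loc[val, panel_ids],
                          annotation, panel.housekeeping_ids)

Xb, yb = lm.build_feature_table(merged, annotation, panel.candidate_ids,
                                "binary")
screen = lm.run_cv(Xb, yb, "binary", n_iterations=10, seed=5)
print(f"screen:  accuracy {screen.accuracy:.1%}, "
      f"AUC {screen.auc_mean:.3f} "
      f"(95% CI {screen.auc_ci[0]:.3f}-{screen.auc_ci[1]:.3f})")
print("confusion (predicted x actual):")
print(screen.confusion.to_string(), "\n")

Xm, ym = lm.build_feature_table(merged, annotation, panel.candidate_ids,
                                "multiclass")
subtype = lm.run_cv(Xm, ym, "multiclass", n_iterations=10, seed=6)
print(f"subtype: accuracy {subtype.accuracy:.1%}")
print("per-class sensitivity:",
      {c: round(s, 3) for c, s in subtype.per_class_sensitivity.items()})
# Accuracy pools held-out predictions over all folds and repeats; the AUC
# summarizes one ROC per repeat from pooled decision scores.
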