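"""Generate a synthetic two-cohort qPCR experiment and inspect its layout.

Builds a reduced cohort (5 diagnostic classes, both cohorts, 3 validation
sites) and prints the plate composition: sample wells in technical
duplicate, 6-point standard dilutions per miRNA per plate, no-template
controls, and spike-in wells.
"""

import lymphomir as lm

config = lm.SimulationConfig(
    n_mirnas=120,
    n_samples_discovery={c: 8 for c in lm.CLASSES},
    n_samples_validation={c: 10 for c in lm.CLASSES},
    seed=1,
)
plates, annotation, truth = lm.simulate_cohort(config)

print("samples per cohort:")
print(annotation.groupby(["cohort", "diagnosis"]).size().unstack(), "\n")
print("well roles:")
print(plates.wells["well_role"].value_counts().to_string(), "\n")
print(f"planted markers per one-vs-rest contrast: "
      f"{ {c: len(m) for c, m in truth.true_markers.items()} }")
print(f"miRNAs engineered to fail the detection filter: "
      f"{len(truth.dropout_mirnas)}")
# The well counts show the assay design: each of the 40 discovery + 50
# validation samples contributes 2 duplicate wells per miRNA plus 3
# spike-ins; each of the 4 RT batches carries 6 standards per miRNA and
# 2 NTCs.
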