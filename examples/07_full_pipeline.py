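"""Run every stage end to end and write the report bundle.

simulate -> quantify -> normalize -> panel -> merge -> classify (screen,
subtype) -> two-stage diagnostic calls -> enrichment -> PCA/clustering
reports, with a manifest recording every stage seed and parameter.
"""

import json
from pathlib import Path

import lymphomir as lm

config = lm.PipelineConfig(
    simulation=lm.SimulationConfig(
        n_mirnas=140,
        n_samples_discovery={c: 8 for c in lm.CLASSES},
        n_samples_validation={c: 12 for c in lm.CLASSES},
        n_markers_per_class=4),
    n_cv_iterations=5, n_permutations=200, n_pathways=30,
    n_pathway_genes=2000, seed=1,
)
outdir = Path("pipeline_output")
bundle = lm.run_pipeline(config, outdir)

manifest = bundle["manifest"]
print("stages completed:", ", ".join(manifest["stages"]))
print("panel tiers:", manifest["stages"]["panel"]["tier_counts"])
print(f"trend concordance: "
      f"{manifest['stages']['panel']['trend_concordant']}/90")
print(f"screen accuracy {bundle['screen'].accuracy:.1%}, "
      f"AUC {bundle['screen'].auc_mean:.3f}; "
      f"subtype accuracy {bundle['subtype'].accuracy:.1%}")
print("two-stage calls (head):")
print(bundle["two_stage"].head().to_string())
print(f"\nreports written to {outdir}/ "
      f"({len(list(outdir.iterdir()))} files)")
# Re-running with the same config and seed reproduces every number in the
# bundle exactly.
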