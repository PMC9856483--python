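"""End-to-end orchestration and reporting.

``run_pipeline`` chains every stage on a synthetic cohort — simulate the
plates, quantify to log2 copies, filter/normalize the discovery cohort,
build the 100-miRNA panel, validate trends in the validation cohort, merge
the cohorts with batch correction, cross-validate the binary screen and the
4-way subtype classifier, apply the two-stage diagnostic rule (subtype only
what the screen calls lymphoma), and run the pathway-enrichment analysis —
writing a manifest plus TSV/JSON reports. Reporting helpers (PCA
coordinates, hierarchical cluster ordering) live here too.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from sklearn.svm import SVC

from . import io as lio
from .simulate import (SimulationConfig, simulate_cohort,
                       simulate_pathway_resources)
from .quantify import quantify_plateset
from .normalize import (filter_detection, global_mean_normalize,
                        zscore_standardize, merge_cohorts)
from .panel import (build_marker_panel, ttest_contrast, ovr_contrasts,
                    ovo_contrasts, validate_trends)
from .classify import build_feature_table, run_cv
from .enrich import run_mirsea

__all__ = ["PipelineConfig", "run_pipeline", "pca_coordinates",
           "cluster_order"]


@dataclass
class PipelineConfig:
    """All stage parameters; unknown keys are rejected on load."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_cv_iterations: int = 100
    outer_folds: int = 4
    n_permutations: int = 10000
    n_pathways: int = 60
    n_pathway_genes: int = 2000
    enrichment_q_cutoff: float = 0.01
    zscore_merged: bool = False   # re-standardize the merged cohort
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValueError(
                f"unknown simulation keys: {sorted(sim_unknown)}")
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["n_samples_discovery"] = dict(
            d["simulation"]["n_samples_discovery"])
        d["simulation"]["n_samples_validation"] = dict(
            d["simulation"]["n_samples_validation"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def pca_coordinates(values: pd.DataFrame, n_components: int = 3
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component sample coordinates via eigendecomposition.

    Deterministic sign convention: each component's largest-magnitude
    loading is made positive. Returns (coordinates, explained variance
    ratio).
    """
    X = values.to_numpy(float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    comps = evecs[:, order]
    for j in range(comps.shape[1]):
        i = int(np.argmax(np.abs(comps[:, j])))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    coords = Xc @ comps
    ratio = evals[order] / evals.sum()
    cols = [f"PC{k + 1}" for k in range(comps.shape[1])]
    return pd.DataFrame(coords, index=values.index, columns=cols), ratio


def cluster_order(values: pd.DataFrame) -> list[str]:
    """Sample ordering from average-linkage Euclidean clustering."""
    link = hierarchy.linkage(values.to_numpy(float), method="average",
                             metric="euclidean")
    return [values.index[i] for i in hierarchy.leaves_list(link)]


def _two_stage_predictions(merged_features, annotation, screen_report,
                           screen_X, screen_y, subtype_X, subtype_y,
                           seed) -> pd.DataFrame:
    """Apply the two-stage diagnostic rule per sample.

    The screen call is the majority vote over the cross-validated held-out
    predictions (reconstructed from the report's fold seeds). Samples the
    screen calls reactive are finalized as RL and skip the subtype stage;
    screen-positive samples get a subtype from a radial-kernel model
    trained on all true-lymphoma samples (using the report's modal tuned
    cost).
    """
    from sklearn.model_selection import StratifiedKFold

    X = screen_X.to_numpy(float)
    y = screen_y.to_numpy()
    votes = pd.DataFrame(0, index=screen_X.index, columns=["RL", "lymphoma"])
    cost = int(pd.Series(screen_report.tuned_costs).mode().iloc[0])
    for rs in screen_report.fold_seeds[:5]:  # 5 repeats suffice for a vote
        skf = StratifiedKFold(4, shuffle=True, random_state=rs)
        for train, test in skf.split(X, y):
            clf = SVC(kernel="rbf", C=cost, gamma="scale")
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            for i, p in zip(test, pred):
                votes.iloc[i, votes.columns.get_loc(p)] += 1
    screen_call = votes.idxmax(axis=1)

    subtype_model = SVC(kernel="rbf", C=cost, gamma="scale",
                        decision_function_shape="ovo")
    subtype_model.fit(subtype_X.to_numpy(float), subtype_y.to_numpy())
    rows = []
    for s in screen_X.index:
        call = screen_call.loc[s]
        if call == "RL":
            final, subtype = "RL", None
        else:
            subtype = subtype_model.predict(
                screen_X.loc[[s]].to_numpy(float))[0]
            final = subtype
        rows.append((s, annotation.loc[s, "diagnosis"], call, subtype, final))
    return pd.DataFrame(rows, columns=[
        "sample_id", "actual", "screen_call", "subtype_call", "final_call"
    ]).set_index("sample_id")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    bundle: dict = {}
    manifest = {"seed": config.seed, "stages": {}, "parameters":
                config.to_dict()}
    try:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        plates, annotation, truth = simulate_cohort(sim_cfg)
        manifest["stages"]["simulate"] = {"seed": sim_cfg.seed,
                                          "n_samples": len(annotation)}
        lio.write_plateset(plates, outdir / "plates.tsv")
        lio.write_annotation(annotation, outdir / "annotation.tsv")
        truth.to_json(outdir / "ground_truth.json")

        stage = "quantify"
        em, curve_qc = quantify_plateset(plates)
        curve_qc.to_csv(outdir / "curve_qc.tsv", sep="\t", index=False)
        lio.write_expression(em, outdir / "log2_copies.tsv",
                             outdir / "detect_mask.tsv")
        manifest["stages"]["quantify"] = {
            "n_mirnas": int(em.values.shape[1]),
            "n_flagged_duplicates": int(len(em.qc_flags))}

        stage = "normalize"
        disc_ids = annotation.index[annotation["cohort"] == "discovery"]
        val_ids = annotation.index[annotation["cohort"] == "validation"]
        disc_em = filter_detection(
            type(em)(em.values.loc[disc_ids], em.mask.loc[disc_ids]))
        disc_norm = zscore_standardize(
            global_mean_normalize(disc_em.values))
        manifest["stages"]["normalize"] = {
            "n_mirnas_detected": int(disc_em.values.shape[1])}

        stage = "panel"
        labels = annotation["diagnosis"]
        mpanel, disc_stats = build_marker_panel(disc_norm, labels)
        mpanel.to_json(outdir / "panel.json")
        mpanel.to_frame().to_csv(outdir / "panel.tsv", sep="\t", index=False)
        disc_stats.to_csv(outdir / "discovery_stats.tsv", sep="\t",
                          index=False)
        # validation profiled on the 100-miRNA panel only
        panel_ids = [e.mirna_id for e in mpanel.entries]
        val_values = em.values.loc[val_ids, panel_ids]
        classes = sorted(labels.unique())
        val_norm = zscore_standardize(global_mean_normalize(val_values))
        val_stats = pd.concat(
            [ttest_contrast(val_norm, labels, c)
             for c in ovr_contrasts(classes) + ovo_contrasts(classes)],
            ignore_index=True)
        trends = validate_trends(disc_stats, val_stats, mpanel)
        trends.to_csv(outdir / "trend_validation.tsv", sep="\t", index=False)
        manifest["stages"]["panel"] = {
            "tier_counts": mpanel.tier_counts(),
            "trend_concordant": int(trends["concordant"].sum()),
            "n_candidates": int(len(trends))}

        stage = "merge"
        merged = merge_cohorts(
            em.values.loc[disc_ids, panel_ids], val_values, annotation,
            mpanel.housekeeping_ids)
        if config.zscore_merged:
            marker_cols = [c for c in merged.columns
                           if c != "tissue_site_numeric"]
            merged[marker_cols] = zscore_standardize(merged[marker_cols])
        lio.write_matrix(merged, outdir / "merged_features.tsv")

        stage = "classify-screen"
        Xb, yb = build_feature_table(
            merged, annotation, mpanel.candidate_ids, "binary")
        screen = run_cv(Xb, yb, "binary",
                        n_iterations=config.n_cv_iterations,
                        outer_folds=config.outer_folds, seed=config.seed)
        screen.confusion.to_csv(outdir / "screen_confusion.tsv", sep="\t")
        manifest["stages"]["classify_screen"] = {
            "seed": config.seed, "accuracy": screen.accuracy,
            "auc_mean": screen.auc_mean}

        stage = "classify-subtype"
        Xm, ym = build_feature_table(
            merged, annotation, mpanel.candidate_ids, "multiclass")
        subtype = run_cv(Xm, ym, "multiclass",
                         n_iterations=config.n_cv_iterations,
                         outer_folds=config.outer_folds,
                         seed=config.seed + 1)
        subtype.confusion.to_csv(outdir / "subtype_confusion.tsv", sep="\t")
        manifest["stages"]["classify_subtype"] = {
            "seed": config.seed + 1, "accuracy": subtype.accuracy}
        with open(outdir / "cv_reports.json", "w") as fh:
            json.dump({"screen": screen.to_dict(),
                       "subtype": subtype.to_dict()}, fh, indent=1)

        stage = "two-stage"
        two_stage = _two_stage_predictions(
            merged, annotation, screen, Xb, yb, Xm, ym, config.seed)
        two_stage.to_csv(outdir / "two_stage_calls.tsv", sep="\t")

        stage = "enrich"
        target_map, pathways = simulate_pathway_resources(
            sim_cfg, n_pathways=config.n_pathways,
            n_genes=config.n_pathway_genes, seed=config.seed + 2,
            true_markers=truth.true_markers)
        lio.write_target_map(target_map, outdir / "target_map.tsv")
        lio.write_gmt(pathways, outdir / "pathways.gmt")
        # rank miRNAs on the full detected set (discovery cohort carries it)
        lymph_stats = ttest_contrast(
            disc_norm,
            labels.map(lambda c: "RL" if c == "RL" else "lymphoma"),
            "lymphoma_vs_RL")
        enr = run_mirsea(lymph_stats, target_map, pathways,
                         n_permutations=config.n_permutations,
                         seed=config.seed + 3)
        enr.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "seed": config.seed + 3,
            "n_pathways_tested": int(len(enr.table)),
            "n_significant": int(
                (enr.table["q"] < config.enrichment_q_cutoff).sum())}

        stage = "report"
        coords, ratio = pca_coordinates(
            zscore_standardize(merged[[c for c in mpanel.candidate_ids
                                       if c in merged.columns]]))
        coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
        order = cluster_order(merged[[c for c in mpanel.candidate_ids
                                      if c in merged.columns]])
        manifest["stages"]["report"] = {
            "pca_variance_ratio": [float(r) for r in ratio],
            "cluster_order_head": order[:5]}
        with open(outdir / "cluster_order.json", "w") as fh:
            json.dump(order, fh)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    bundle.update(
        plates=plates, annotation=annotation, truth=truth,
        expression=em, panel=mpanel, discovery_stats=disc_stats,
        validation_stats=val_stats, trends=trends, merged=merged,
        screen=screen, subtype=subtype, two_stage=two_stage,
        enrichment=enr, pca=coords, pca_variance_ratio=ratio,
        cluster_order=order, manifest=manifest)
    return bundle
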