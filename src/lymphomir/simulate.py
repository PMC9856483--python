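"""Synthetic RT-qPCR cohort generator.

Emulates a multiplexed miRNA profiling experiment on FFPE lymphoid tissue:
five diagnostic classes (reactive lymphoid proliferation RL and four small
B-cell lymphoma subtypes SLL/FL/MCL/MZL), a single-site discovery cohort and
a three-site validation cohort, per-site batch effects, per-sample workflow
variation monitored by spike-ins, six-point 10-fold standard-dilution series,
no-template controls, and technical duplicate sample wells.

The latent signal lives in log2 copy-number space:

    log2(copies)[s, m] = baseline[m] + class_effect + batch_gamma[plate, m]
                         + biological noise (sd sigma[m] * delta[plate, m])

and is read out as a threshold cycle via a perfect-efficiency curve

    Ct = intercept[m] - log2(copies) + workflow_shift[s] + replicate noise,

so the inverse mapping used by the quantification stage is analytically
checkable. Wells whose Ct would reach the no-template-control level are
emitted at exactly the NTC Ct (undetected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .quantify import PlateSet

__all__ = [
    "CLASSES",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_pathway_resources",
]

#: Canonical diagnostic classes: reactive control + four lymphoma subtypes.
CLASSES = ("RL", "SLL", "FL", "MCL", "MZL")
LYMPHOMA_CLASSES = ("SLL", "FL", "MCL", "MZL")

#: Collection sites of the validation cohort (discovery is NUH only).
SITES = ("NUH", "TTSH", "UMMC")

# Nodal / extranodal tissue-site counts per class, as recruited.
_TISSUE_SPLIT = {
    "discovery": {
        "SLL": (20, 3), "FL": (5, 16), "MCL": (12, 8), "MZL": (0, 19), "RL": (15, 2),
    },
    "validation": {
        "SLL": (14, 6), "FL": (53, 21), "MCL": (13, 9), "MZL": (5, 69), "RL": (54, 38),
    },
}

_DEFAULT_DISCOVERY = {"SLL": 23, "FL": 21, "MCL": 20, "MZL": 19, "RL": 17}
_DEFAULT_VALIDATION = {"SLL": 20, "FL": 74, "MCL": 22, "MZL": 74, "RL": 92}

#: 10-fold standard dilution series, copies per reaction.
STANDARD_COPIES = tuple(10.0 ** k for k in range(1, 7))
#: Baseline Ct of the three spike-in species (before workflow shifts).
SPIKE_BASE_CT = (21.0, 24.0, 27.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Counts mirror the recruited cohorts (discovery n=100, validation n=282);
    noise scales are in the units of the quantity they perturb (log2 copies
    for biological/batch terms, Ct cycles for workflow/replicate terms).
    """

    n_mirnas: int = 360
    n_samples_discovery: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_DISCOVERY))
    n_samples_validation: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_VALIDATION))
    n_markers_per_class: int = 12
    effect_size: float = 1.5          # log2-copy shift of true markers
    batch_shift_sd: float = 0.4       # sd of per-plate additive log2 shifts
    batch_scale_sd: float = 0.1       # sd of log per-plate noise inflation
    spike_in_sd: float = 0.3          # per-sample workflow shift, Ct units
    replicate_sd: float = 0.15        # technical duplicate noise, Ct units
    biological_sd: float = 0.6        # inter-sample log2-copy variability
    dropout_fraction: float = 0.13    # miRNAs engineered to fail detection
    ntc_ct: float = 38.0
    curve_intercept: float = 40.0     # Ct at 1 copy, before per-miRNA jitter
    intercept_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        for name, counts in (("n_samples_discovery", self.n_samples_discovery),
                             ("n_samples_validation", self.n_samples_validation)):
            unknown = set(counts) - set(CLASSES)
            if unknown:
                raise ValueError(
                    f"{name} names unknown classes {sorted(unknown)}; "
                    f"valid classes are {CLASSES}")
            if any(v < 1 for v in counts.values()):
                raise ValueError(f"{name} counts must be >= 1")
        for name in ("effect_size", "batch_shift_sd", "batch_scale_sd",
                     "spike_in_sd", "replicate_sd", "biological_sd",
                     "intercept_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.n_markers_per_class < 0:
            raise ValueError("n_markers_per_class must be >= 0")

    @property
    def mirna_ids(self) -> list[str]:
        width = max(3, len(str(self.n_mirnas)))
        return [f"miR-{i:0{width}d}" for i in range(1, self.n_mirnas + 1)]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks.

    ``true_markers`` maps each one-vs-rest contrast (``"<class>_vs_rest"``)
    to ``{mirna_id: +1 | -1}`` (direction of the shift in the class of
    interest). ``true_log2_copies`` is the latent per-(sample, miRNA) signal
    including batch effects — exactly what quantification should recover.
    ``true_log2_copies_nobatch`` strips the batch term (the batch-correction
    recovery target).
    """

    true_markers: dict[str, dict[str, int]]
    true_batch_params: dict[str, dict[str, list[float]]]
    true_log2_copies: pd.DataFrame
    true_log2_copies_nobatch: pd.DataFrame
    workflow_shifts: pd.Series
    dropout_mirnas: list[str]

    def marker_direction(self, contrast: str, mirna: str) -> int:
        """Planted direction for an ovr or ovo contrast (0 if not a marker)."""
        if contrast.endswith("_vs_rest"):
            return self.true_markers.get(contrast, {}).get(mirna, 0)
        a, b = contrast.split("_vs_")
        d = self.true_markers.get(f"{a}_vs_rest", {}).get(mirna, 0)
        if d:
            return d
        return -self.true_markers.get(f"{b}_vs_rest", {}).get(mirna, 0)

    def to_json(self, path) -> None:
        payload = {
            "true_markers": self.true_markers,
            "true_batch_params": self.true_batch_params,
            "dropout_mirnas": self.dropout_mirnas,
            "workflow_shifts": self.workflow_shifts.to_dict(),
            "true_log2_copies": self.true_log2_copies.to_dict(orient="split"),
            "true_log2_copies_nobatch":
                self.true_log2_copies_nobatch.to_dict(orient="split"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _tissue_sites(cohort: str, cls: str, n: int) -> list[str]:
    """Nodal/extranodal assignment scaled from the recruited proportions."""
    nodal, extranodal = _TISSUE_SPLIT[cohort][cls]
    frac = nodal / (nodal + extranodal)
    n_nodal = int(round(frac * n))
    return ["nodal"] * n_nodal + ["extranodal"] * (n - n_nodal)


def simulate_cohort(config: SimulationConfig):
    """Generate plates, annotation, and ground truth for both cohorts.

    Returns
    -------
    (PlateSet, pandas.DataFrame, GroundTruth)
        The annotation frame is indexed by sample id with columns
        ``diagnosis``, ``tissue_site``, ``collection_site``, ``cohort``.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = config.mirna_ids
    n_m = config.n_mirnas

    # --- per-miRNA latent parameters -------------------------------------
    intercept = config.curve_intercept + rng.normal(
        0.0, config.intercept_jitter_sd, n_m)
    baseline = rng.uniform(6.0, 14.0, n_m)
    sigma = rng.uniform(0.5, 1.5, n_m) * config.biological_sd

    # --- samples and annotation ------------------------------------------
    rows = []
    for cohort, counts, prefix in (
            ("discovery", config.n_samples_discovery, "D"),
            ("validation", config.n_samples_validation, "V")):
        idx = 0
        for cls in CLASSES:
            n = counts.get(cls, 0)
            if n == 0:
                continue
            tissues = _tissue_sites(cohort, cls, n)
            for t in tissues:
                idx += 1
                rows.append((f"{prefix}{idx:03d}", cls, t, cohort))
    annotation = pd.DataFrame(
        rows, columns=["sample_id", "diagnosis", "tissue_site", "cohort"]
    ).set_index("sample_id")
    # collection sites: discovery all NUH; validation spread over 3 sites
    sites = np.where(
        annotation["cohort"] == "discovery", "NUH",
        rng.choice(SITES, size=len(annotation)))
    annotation["collection_site"] = sites
    annotation = annotation[["diagnosis", "tissue_site", "collection_site", "cohort"]]
    samples = annotation.index.to_numpy()
    n_s = len(samples)

    # --- planted markers ---------------------------------------------------
    n_per = config.n_markers_per_class
    eligible = np.arange(n_m)
    marker_pool = rng.choice(eligible, size=min(5 * n_per, n_m), replace=False)
    true_markers: dict[str, dict[str, int]] = {}
    class_effect = np.zeros((n_s, n_m))
    class_of = annotation["diagnosis"].to_numpy()
    for ci, cls in enumerate(CLASSES):
        chosen = marker_pool[ci * n_per:(ci + 1) * n_per]
        signs = np.array([1 if j < (n_per + 1) // 2 else -1
                          for j in range(len(chosen))])
        true_markers[f"{cls}_vs_rest"] = {
            mirnas[m]: int(s) for m, s in zip(chosen, signs)}
        in_class = class_of == cls
        for m, s in zip(chosen, signs):
            class_effect[in_class, m] += s * config.effect_size

    # --- plates (one RT batch per cohort x site) and batch effects ---------
    plate_of = np.array([
        f"{c[:4]}-{s}" for c, s in
        zip(annotation["cohort"], annotation["collection_site"])])
    plates = sorted(set(plate_of))
    gamma = {p: rng.normal(0.0, config.batch_shift_sd, n_m) for p in plates}
    delta = {p: np.exp(rng.normal(0.0, config.batch_scale_sd, n_m))
             for p in plates}
    batch_term = np.stack([gamma[p] for p in plate_of])
    noise_scale = np.stack([delta[p] for p in plate_of]) * sigma

    noise = rng.normal(0.0, 1.0, (n_s, n_m)) * noise_scale
    latent_nobatch = baseline + class_effect + noise
    latent = latent_nobatch + batch_term

    # --- engineered dropout ------------------------------------------------
    n_drop = int(round(config.dropout_fraction * n_m))
    non_marker = np.setdiff1d(eligible, marker_pool)
    drop_idx = rng.choice(non_marker, size=min(n_drop, len(non_marker)),
                          replace=False)
    cohort_of = annotation["cohort"].to_numpy()
    for m in drop_idx:
        f = rng.uniform(0.15, 0.8)
        for cohort in ("discovery", "validation"):
            members = np.flatnonzero(cohort_of == cohort)
            if len(members) == 0:
                continue
            k = int(np.ceil(f * len(members)))
            forced = rng.choice(members, size=k, replace=False)
            latent[forced, m] = -5.0
            latent_nobatch[forced, m] = -5.0

    # --- workflow (spike-in) shifts and Ct read-out ------------------------
    w = rng.normal(0.0, config.spike_in_sd, n_s)
    well_rows = []

    # sample wells in technical duplicate
    for rep in (1, 2):
        rep_noise = rng.normal(0.0, config.replicate_sd, (n_s, n_m))
        ct = intercept - latent + w[:, None] + rep_noise
        ct = np.minimum(ct, config.ntc_ct)  # undetected floor
        well_rows.append(pd.DataFrame({
            "plate_id": np.repeat(plate_of, n_m),
            "well_role": "sample",
            "sample_id": np.repeat(samples, n_m),
            "mirna_id": np.tile(mirnas, n_s),
            "replicate": rep,
            "ct": ct.ravel(),
            "known_copies": np.nan,
        }))

    # spike-in series: three species, one well each per sample
    for k, base in enumerate(SPIKE_BASE_CT, start=1):
        ct = base + w + rng.normal(0.0, config.replicate_sd, n_s)
        well_rows.append(pd.DataFrame({
            "plate_id": plate_of,
            "well_role": "spike",
            "sample_id": samples,
            "mirna_id": f"spike-{k}",
            "replicate": 1,
            "ct": ct,
            "known_copies": np.nan,
        }))

    # per-plate standard series (6 ten-fold points per miRNA) and 2 NTC wells
    for p in plates:
        for di, copies in enumerate(STANDARD_COPIES, start=1):
            ct = (intercept - np.log2(copies)
                  + rng.normal(0.0, config.replicate_sd, n_m))
            well_rows.append(pd.DataFrame({
                "plate_id": p,
                "well_role": "standard",
                "sample_id": f"STD{di}",
                "mirna_id": mirnas,
                "replicate": 1,
                "ct": ct,
                "known_copies": copies,
            }))
        well_rows.append(pd.DataFrame({
            "plate_id": p,
            "well_role": "ntc",
            "sample_id": [f"NTC{i}" for i in (1, 2)],
            "mirna_id": "",
            "replicate": 1,
            "ct": config.ntc_ct,
            "known_copies": np.nan,
        }))

    wells = pd.concat(well_rows, ignore_index=True)
    plateset = PlateSet(wells=wells)

    truth = GroundTruth(
        true_markers=true_markers,
        true_batch_params={
            p: {"gamma": gamma[p].tolist(), "delta": delta[p].tolist()}
            for p in plates},
        true_log2_copies=pd.DataFrame(latent, index=samples, columns=mirnas),
        true_log2_copies_nobatch=pd.DataFrame(
            latent_nobatch, index=samples, columns=mirnas),
        workflow_shifts=pd.Series(w, index=samples, name="workflow_shift_ct"),
        dropout_mirnas=[mirnas[m] for m in sorted(drop_idx)],
    )
    return plateset, annotation, truth


def simulate_pathway_resources(
    config: SimulationConfig,
    n_pathways: int = 50,
    n_genes: int = 4000,
    seed: int | None = None,
    true_markers=None,
    n_enriched: int = 5,
    overlap: float = 0.9,
    targets_per_mirna: tuple[int, int] = (5, 30),
):
    """Generate a miRNA→gene target table plus GMT-style pathway sets.

    Targeting is sparse, as in strong-evidence interaction catalogues: each
    miRNA targets a handful of genes in a large universe, so pathway
    membership (>= 1 validated target in the set) is informative rather
    than near-universal.

    ``n_enriched`` pathways are planted to be enriched for targets of the
    differential miRNAs: ``true_markers`` is either the contrast map
    produced by :func:`simulate_cohort` (the union of marker ids is used)
    or an iterable of miRNA ids; a fraction ``overlap`` of each planted
    pathway's genes is drawn from those markers' targets. The remaining
    pathways are random gene draws whose targeting-miRNA counts span below
    10 and (when ``config.n_mirnas`` allows) above 500, exercising the
    enrichment stage's size filter.

    Returns ``(target_map, pathways)`` where ``target_map`` is a DataFrame
    with columns (mirna_id, gene_id, evidence) and ``pathways`` maps
    pathway name -> (source_tag, gene set).
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mirnas = config.mirna_ids
    genes = np.array([f"GENE{i:05d}" for i in range(1, n_genes + 1)])

    lo, hi = targets_per_mirna
    target_rows = []
    target_sets: dict[str, np.ndarray] = {}
    for m in mirnas:
        k = int(rng.integers(lo, hi + 1))
        tg = rng.choice(genes, size=min(k, n_genes), replace=False)
        target_sets[m] = tg
        target_rows.extend((m, g, "strong") for g in tg)
    target_map = pd.DataFrame(
        target_rows, columns=["mirna_id", "gene_id", "evidence"])

    if true_markers and isinstance(true_markers, Mapping):
        marker_ids = sorted({m for d in true_markers.values() for m in d})
    elif true_markers:
        marker_ids = sorted(true_markers)
    else:
        marker_ids = []
    marker_gene_pool = (
        np.unique(np.concatenate([target_sets[m] for m in marker_ids]))
        if marker_ids else np.array([], dtype=genes.dtype))

    sources = ("KEGG", "REACTOME", "PID", "BIOCARTA")
    pathways: dict[str, tuple[str, set[str]]] = {}
    n_enriched = min(n_enriched, n_pathways) if len(marker_gene_pool) else 0
    for i in range(n_pathways):
        src = sources[i % len(sources)]
        if i < n_enriched:
            # small sets dominated by marker targets: markers are members
            # with strong targeting p-values, chance members stay few
            size = int(rng.integers(30, 60))
            k_marked = min(int(round(overlap * size)), len(marker_gene_pool))
            core = rng.choice(marker_gene_pool, size=k_marked, replace=False)
            rest = rng.choice(genes, size=size - k_marked, replace=False)
            members = set(core) | set(rest)
            name = f"{src}_PLANTED_{i + 1:02d}"
        else:
            # size ladder: tiny sets (few targeting miRNAs), mid-size sets,
            # and — when the miRNA universe can push a set past the upper
            # size filter — one near-universe set (> 500 targeting miRNAs)
            if i == n_pathways - 1 and n_genes > 50 and len(mirnas) > 500:
                size = int(0.9 * n_genes)
            elif (i - n_enriched) % 7 == 0:
                size = int(rng.integers(2, 6))
            else:
                size = int(rng.integers(60, 300))
            members = set(rng.choice(genes, size=min(size, n_genes),
                                     replace=False))
            name = f"{src}_PATHWAY_{i + 1:02d}"
        pathways[name] = (src, members)
    return target_map, pathways
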