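"""Absolute quantification of miRNA RT-qPCR data.

Turns raw threshold-cycle (Ct) observations into a samples x miRNAs matrix
of log2 absolute copy numbers: spike-in correction for per-sample workflow
variation, least-squares standard curves from 10-fold dilution series,
no-template-control (NTC) based detectability calls, technical-duplicate
averaging on the Ct scale, and standard-curve interpolation to copies.

Conventions fixed here (qPCR practice where the upstream protocol leaves
a choice): duplicates are averaged on the Ct scale; a duplicate pair with a
single detectable member uses that member; detectability is judged against
the *minimum* NTC Ct of the well's plate (the strictest reading of "higher
than the NTCs"); undetected entries are imputed at the plate's detection
limit (the copy number interpolated at the minimum NTC Ct) and flagged
False in the detectability mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateSet",
    "StandardCurve",
    "ExpressionMatrix",
    "correct_spike_ins",
    "fit_standard_curve",
    "fit_standard_curves",
    "call_detectable",
    "interpolate_copies",
    "build_expression_matrix",
    "quantify_plateset",
]

WELL_COLUMNS = ("plate_id", "well_role", "sample_id", "mirna_id",
                "replicate", "ct", "known_copies")
WELL_ROLES = ("sample", "standard", "ntc", "spike")

#: Ct assigned to an NTC well that never amplified.
MISSING_NTC_CT = 40.0


@dataclass
class PlateSet:
    """Long-format collection of qPCR wells across plates.

    ``wells`` columns: plate_id, well_role in {sample, standard, ntc, spike},
    sample_id (control id for non-sample wells), mirna_id, replicate, ct,
    known_copies (standards only; NaN elsewhere). A missing Ct is NaN.
    """

    wells: pd.DataFrame
    spike_corrected: bool = False

    def __post_init__(self) -> None:
        missing = set(WELL_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"PlateSet wells missing columns {sorted(missing)}")
        bad_roles = set(self.wells["well_role"].unique()) - set(WELL_ROLES)
        if bad_roles:
            raise ValueError(f"unknown well roles {sorted(bad_roles)}")
        ct = self.wells["ct"]
        out = ct.notna() & ((ct < 0) | (ct > 45))
        if out.any():
            raise ValueError(
                f"{int(out.sum())} wells have Ct outside [0, 45] and are not "
                "flagged missing")

    def ntc_floor(self) -> pd.Series:
        """Minimum NTC Ct per plate (missing NTC amplification -> 40)."""
        ntc = self.wells[self.wells["well_role"] == "ntc"]
        floor = (ntc.assign(ct=ntc["ct"].fillna(MISSING_NTC_CT))
                 .groupby("plate_id")["ct"].min())
        return floor

    def copy(self) -> "PlateSet":
        return PlateSet(self.wells.copy(), self.spike_corrected)


@dataclass
class StandardCurve:
    """Least-squares line Ct = intercept + slope * log10(copies)."""

    mirna_id: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency: 1.0 is perfect per-cycle doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(
                f"standard curve for {self.mirna_id}: slope must be negative "
                f"(got {self.slope})")


@dataclass
class ExpressionMatrix:
    """samples x miRNAs log2 copy numbers with a detectability mask."""

    values: pd.DataFrame
    mask: pd.DataFrame
    qc_flags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "mirna_id", "delta_ct"]))

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not (self.values.index.equals(self.mask.index)
                and self.values.columns.equals(self.mask.columns)):
            raise ValueError("values and mask axis labels differ")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def mirnas(self) -> pd.Index:
        return self.values.columns

    def subset_mirnas(self, ids) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(self.values[ids].copy(),
                                self.mask[ids].copy(), self.qc_flags)


def correct_spike_ins(plates: PlateSet) -> PlateSet:
    """Remove per-sample workflow variation using spike-in wells.

    Each sample's detectable sample-well Cts are shifted by minus the
    deviation of its mean spike-in Ct from the cohort median of those means.
    Spike-in wells are retained unchanged for audit; the returned PlateSet
    is flagged so a second application is a no-op. Undetected sample wells
    (Ct at or above the plate's NTC floor) are sentinels, not measurements,
    and are left untouched so detectability calls are unaffected.
    """
    if plates.spike_corrected:
        return plates
    wells = plates.wells.copy()
    spikes = wells[wells["well_role"] == "spike"]
    sample_ids = wells.loc[wells["well_role"] == "sample", "sample_id"].unique()
    spike_means = spikes.groupby("sample_id")["ct"].mean()
    missing = set(sample_ids) - set(spike_means.index)
    if missing:
        raise ValueError(
            f"samples without spike-in wells: {sorted(missing)[:5]}"
            f"{' ...' if len(missing) > 5 else ''}")
    shift = spike_means - spike_means.loc[list(sample_ids)].median()

    floor = plates.ntc_floor()
    is_sample = wells["well_role"] == "sample"
    detectable = is_sample & (
        wells["ct"] < wells["plate_id"].map(floor).fillna(MISSING_NTC_CT))
    wells.loc[detectable, "ct"] = (
        wells.loc[detectable, "ct"]
        - wells.loc[detectable, "sample_id"].map(shift))
    return PlateSet(wells, spike_corrected=True)


def fit_standard_curve(series: pd.DataFrame,
                       mirna_id: str | None = None) -> StandardCurve:
    """Fit Ct against log10(known copies) for one miRNA's dilution series.

    ``series`` needs columns ``ct`` and ``known_copies``. At least two
    distinct dilution points with finite Ct are required; with exactly two
    the fit is saturated (r² = 1).
    """
    s = series.dropna(subset=["ct", "known_copies"])
    if mirna_id is None:
        ids = s["mirna_id"].unique() if "mirna_id" in s else ["?"]
        mirna_id = ids[0] if len(ids) else "?"
    x = np.log10(s["known_copies"].to_numpy(float))
    y = s["ct"].to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValueError(
            f"standard series for {mirna_id} has fewer than 2 distinct "
            "dilution points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
    return StandardCurve(mirna_id, float(slope), float(intercept), float(r2))


def fit_standard_curves(plates: PlateSet) -> dict[str, StandardCurve]:
    """Per-miRNA curves pooling standard wells across plates."""
    std = plates.wells[plates.wells["well_role"] == "standard"]
    return {m: fit_standard_curve(grp, m)
            for m, grp in std.groupby("mirna_id", sort=True)}


def call_detectable(ct: float, ntc_cts) -> bool:
    """True iff the Ct beat every no-template control on its plate."""
    ntc = [MISSING_NTC_CT if (c is None or np.isnan(c)) else c for c in ntc_cts]
    if ct is None or np.isnan(ct):
        return False
    return bool(ct < min(ntc))


def interpolate_copies(ct, curve: StandardCurve):
    """Absolute copies from a Ct via the standard curve (10^((ct-b)/m))."""
    return 10.0 ** ((np.asarray(ct, float) - curve.intercept) / curve.slope)


def build_expression_matrix(plates: PlateSet,
                            curves: dict[str, StandardCurve],
                            dup_flag_delta_ct: float = 1.0) -> ExpressionMatrix:
    """Collapse duplicate sample wells into log2 copy numbers.

    Per (sample, miRNA): detectability is called per well against the
    plate's NTC floor; the mean Ct of detectable wells is interpolated to
    copies and stored as log2(copies) with mask True. Pairs with no
    detectable well get mask False and the plate's detection-limit value.
    Duplicate pairs of detectable wells differing by more than
    ``dup_flag_delta_ct`` cycles are recorded in ``qc_flags``.
    """
    wells = plates.wells
    sw = wells[wells["well_role"] == "sample"].copy()
    uncurved = set(sw["mirna_id"].unique()) - set(curves)
    if uncurved:
        raise ValueError(f"no standard curve for miRNAs {sorted(uncurved)[:5]}"
                         f"{' ...' if len(uncurved) > 5 else ''}")

    floor = plates.ntc_floor()
    sw["ntc_floor"] = sw["plate_id"].map(floor).fillna(MISSING_NTC_CT)
    sw["detectable"] = sw["ct"].notna() & (sw["ct"] < sw["ntc_floor"])
    sw["ct_det"] = sw["ct"].where(sw["detectable"])

    grp = sw.groupby(["sample_id", "mirna_id"], sort=True)
    agg = grp.agg(
        mean_ct=("ct_det", "mean"),
        n_det=("detectable", "sum"),
        lo=("ct_det", "min"),
        hi=("ct_det", "max"),
        ntc_floor=("ntc_floor", "min"),
    ).reset_index()

    slopes = pd.Series({m: c.slope for m, c in curves.items()})
    intercepts = pd.Series({m: c.intercept for m, c in curves.items()})
    m_slope = agg["mirna_id"].map(slopes)
    m_inter = agg["mirna_id"].map(intercepts)

    detected = agg["n_det"] > 0
    log2_copies = ((agg["mean_ct"] - m_inter) / m_slope) * np.log2(10.0)
    limit = ((agg["ntc_floor"] - m_inter) / m_slope) * np.log2(10.0)
    agg["value"] = np.where(detected, log2_copies, limit)
    agg["mask"] = detected

    flagged = agg[(agg["n_det"] >= 2)
                  & ((agg["hi"] - agg["lo"]) > dup_flag_delta_ct)]
    qc = flagged.assign(delta_ct=flagged["hi"] - flagged["lo"])[
        ["sample_id", "mirna_id", "delta_ct"]].reset_index(drop=True)

    values = agg.pivot(index="sample_id", columns="mirna_id", values="value")
    mask = agg.pivot(index="sample_id", columns="mirna_id", values="mask")
    # keep plate emission order for samples, sorted miRNAs for columns
    sample_order = sw["sample_id"].drop_duplicates().to_numpy()
    values = values.loc[sample_order]
    mask = mask.loc[sample_order].astype(bool)
    values.index.name = mask.index.name = "sample_id"
    values.columns.name = mask.columns.name = None
    return ExpressionMatrix(values, mask, qc)


def quantify_plateset(plates: PlateSet) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Spike-correct, fit curves, and build the expression matrix.

    Returns the matrix and a per-miRNA curve QC table
    (slope, efficiency, r_squared).
    """
    corrected = correct_spike_ins(plates)
    curves = fit_standard_curves(corrected)
    em = build_expression_matrix(corrected, curves)
    qc = pd.DataFrame(
        [(m, c.slope, c.efficiency, c.r_squared)
         for m, c in sorted(curves.items())],
        columns=["mirna_id", "slope", "efficiency", "r_squared"])
    return em, qc
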