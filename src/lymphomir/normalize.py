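"""Normalization and batch correction of log2 copy-number matrices.

Stages, in the order the analysis applies them: detection filtering
(miRNAs undetected in more than 10% of discovery samples are dropped),
global-mean normalization (each sample centred on its mean log2 expression,
the qPCR analogue of Mestdagh-style global normalization), per-miRNA
Z-score standardization, housekeeping-set normalization (used when the
validation cohort is profiled on the reduced panel), and parametric
empirical-Bayes location/scale batch correction (ComBat) with the
collection site as batch and tissue site + diagnostic class protected as
covariates.

All matrix arguments are pandas DataFrames of shape samples x miRNAs
unless an :class:`~lymphomir.quantify.ExpressionMatrix` is stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

__all__ = [
    "NormalizationReport",
    "filter_detection",
    "global_mean_normalize",
    "zscore_standardize",
    "housekeeping_normalize",
    "combat_correct",
    "merge_cohorts",
]


@dataclass
class NormalizationReport:
    n_mirnas_in: int
    n_mirnas_retained: int
    per_sample_global_means: pd.Series | None = None
    housekeeping_ids: list[str] = field(default_factory=list)
    batch_gamma: pd.DataFrame | None = None   # batches x miRNAs, additive
    batch_delta2: pd.DataFrame | None = None  # batches x miRNAs, scale

    def __post_init__(self) -> None:
        if self.n_mirnas_retained > self.n_mirnas_in:
            raise ValueError("retained more miRNAs than supplied")


def filter_detection(matrix: ExpressionMatrix,
                     max_undetected_fraction: float = 0.10) -> ExpressionMatrix:
    """Drop miRNAs undetected in more than the allowed fraction of samples.

    The boundary is inclusive: a miRNA undetected in exactly 10% of samples
    is retained ("not detected in >10%" removes it only beyond the bound).
    Column order is preserved.
    """
    undet = 1.0 - matrix.mask.mean(axis=0)
    keep = matrix.mirnas[(undet <= max_undetected_fraction).to_numpy()]
    if len(keep) == 0:
        raise ValueError(
            "no miRNA passes the detection filter; relax "
            f"max_undetected_fraction (= {max_undetected_fraction})")
    return matrix.subset_mirnas(keep)


def global_mean_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's mean log2 expression from its values."""
    if values.shape[1] < 2:
        raise ValueError("global normalization needs >= 2 miRNAs")
    return values.sub(values.mean(axis=1), axis=0)


def zscore_standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale each miRNA to mean 0, sample sd 1 (ddof=1)."""
    sd = values.std(axis=0, ddof=1)
    zero = sd[~(sd > 0)].index.tolist()
    if zero:
        raise ValueError(
            f"zero-variance miRNAs cannot be Z-scored: {zero[:10]}"
            f"{' ...' if len(zero) > 10 else ''}")
    return values.sub(values.mean(axis=0), axis=1).div(sd, axis=1)


def housekeeping_normalize(values: pd.DataFrame,
                           housekeeping_ids) -> pd.DataFrame:
    """Subtract the per-sample mean of the housekeeping set from all values."""
    housekeeping_ids = list(housekeeping_ids)
    missing = [h for h in housekeeping_ids if h not in values.columns]
    if missing:
        raise ValueError(f"housekeeping miRNAs absent from matrix: {missing}")
    ref = values[housekeeping_ids].mean(axis=1)
    return values.sub(ref, axis=0)


def _design_matrix(covariates: pd.DataFrame | None,
                   index: pd.Index) -> np.ndarray:
    """Covariate design (no intercept column; categorical -> dummy-coded)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((len(index), 0))
    cov = covariates.loc[index]
    parts = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype.kind in "biufc":
            parts.append(s.to_numpy(float).reshape(-1, 1))
        else:
            d = pd.get_dummies(s, drop_first=True).to_numpy(float)
            parts.append(d)
    return np.hstack(parts) if parts else np.empty((len(index), 0))


def combat_correct(values: pd.DataFrame,
                   batch_labels: pd.Series,
                   covariates: pd.DataFrame | None = None,
                   ) -> tuple[pd.DataFrame, NormalizationReport]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardizes each miRNA under a model with batch indicators and the
    protected covariates, estimates per-batch per-miRNA additive (gamma)
    and multiplicative (delta^2) batch effects, shrinks them across miRNAs
    with parametric EB priors (normal for gamma, inverse-gamma for
    delta^2), removes the shrunken effects and restores the covariate
    structure. A single batch returns the input unchanged.
    """
    batch_labels = batch_labels.loc[values.index]
    batches = sorted(batch_labels.unique())
    n, g = values.shape
    if len(batches) < 2:
        report = NormalizationReport(g, g)
        return values.copy(), report
    counts = batch_labels.value_counts()
    singleton = counts[counts < 2].index.tolist()
    if singleton:
        raise ValueError(f"batches with a single sample: {singleton}")

    X = values.to_numpy(float)                      # n x g
    batch_design = pd.get_dummies(batch_labels)[batches].to_numpy(float)
    cov_design = _design_matrix(covariates, values.index)
    design = np.hstack([batch_design, cov_design])  # n x (b + c)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design: covariates are confounded with batch")

    # per-miRNA OLS fit of batch + covariate model
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)  # (b+c) x g
    n_batch = counts.loc[batches].to_numpy(float)
    n_b = len(batches)
    # grand mean: batch coefficients averaged with batch-size weights
    grand = (n_batch / n) @ beta[:n_b]                 # g
    stand_mean = np.outer(np.ones(n), grand)
    if cov_design.shape[1]:
        stand_mean = stand_mean + cov_design @ beta[n_b:]
    resid = X - design @ beta
    var_pooled = (resid ** 2).sum(axis=0) / n          # g
    var_pooled = np.maximum(var_pooled, 1e-12)
    s_data = (X - stand_mean) / np.sqrt(var_pooled)

    # batch effect estimates on standardized data
    member = [batch_labels.to_numpy() == b for b in batches]
    gamma_hat = np.vstack([s_data[m].mean(axis=0) for m in member])
    delta_hat = np.vstack([s_data[m].var(axis=0, ddof=1) for m in member])

    # parametric EB priors across miRNAs
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    # inverse-gamma moments for the scale prior
    d_bar = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    lam = (2 * s2 + d_bar ** 2) / np.maximum(s2, 1e-12)
    theta = (d_bar * s2 + d_bar ** 3) / np.maximum(s2, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, m in enumerate(member):
        ni = m.sum()
        g_new, d_new = gamma_hat[i].copy(), delta_hat[i].copy()
        # iterate the coupled EB posterior updates to convergence
        for _ in range(100):
            g_prev, d_prev = g_new, d_new
            g_new = ((tau2[i] * ni * gamma_hat[i] + d_new * gamma_bar[i])
                     / (tau2[i] * ni + d_new))
            sse = ((s_data[m] - np.outer(np.ones(ni), g_new)) ** 2).sum(axis=0)
            d_new = (theta[i] + 0.5 * sse) / (ni / 2 + lam[i] - 1)
            if (np.max(np.abs(g_new - g_prev)) < 1e-8
                    and np.max(np.abs(d_new - d_prev)) < 1e-8):
                break
        gamma_star[i], delta_star[i] = g_new, d_new

    adjusted = s_data.copy()
    for i, m in enumerate(member):
        adjusted[m] = (s_data[m] - gamma_star[i]) / np.sqrt(delta_star[i])
    corrected = adjusted * np.sqrt(var_pooled) + stand_mean

    report = NormalizationReport(
        g, g,
        batch_gamma=pd.DataFrame(gamma_star, index=batches,
                                 columns=values.columns),
        batch_delta2=pd.DataFrame(delta_star, index=batches,
                                  columns=values.columns),
    )
    return pd.DataFrame(corrected, index=values.index,
                        columns=values.columns), report


def merge_cohorts(discovery: pd.DataFrame,
                  validation: pd.DataFrame,
                  annotation: pd.DataFrame,
                  housekeeping_ids,
                  tissue_feature: str = "tissue_site_numeric",
                  ) -> pd.DataFrame:
    """Combine the two cohorts on their shared miRNA panel.

    Each cohort is housekeeping-normalized; the validation cohort is
    batch-corrected across its collection sites; then a second correction
    removes the cohort-level batch. Tissue site and diagnostic class are
    protected covariates throughout. A numeric tissue-site indicator
    (nodal=0, extranodal=1) is appended as the final column.
    """
    shared = [m for m in discovery.columns if m in set(validation.columns)]
    if not shared:
        raise ValueError("cohorts share no miRNAs")
    disc = housekeeping_normalize(discovery[shared], housekeeping_ids)
    val = housekeeping_normalize(validation[shared], housekeeping_ids)

    ann_val = annotation.loc[val.index]
    cov_val = ann_val[["tissue_site", "diagnosis"]]
    if ann_val["collection_site"].nunique() > 1:
        val, _ = combat_correct(val, ann_val["collection_site"], cov_val)

    merged = pd.concat([disc, val], axis=0)
    ann = annotation.loc[merged.index]
    cohort = ann["cohort"]
    if cohort.nunique() > 1:
        merged, _ = combat_correct(
            merged, cohort, ann[["tissue_site", "diagnosis"]])
    merged[tissue_feature] = (
        ann["tissue_site"].map({"nodal": 0, "extranodal": 1}).astype(int))
    return merged
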