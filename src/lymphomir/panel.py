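"""Differential-expression testing and marker-panel construction.

The diagnostic panel has three tiers built from the discovery cohort:

* ``ovr`` — for each of the five diagnostic classes, the 3 most
  significantly up- and 3 most significantly down-regulated miRNAs in a
  one-vs-rest Student's t-test (30 markers);
* ``ovo`` — the same 3-up/3-down selection for each of the 10 class pairs
  (60 markers);
* ``housekeeping`` — the 10 lowest-variance miRNAs outside the marker
  tiers.

The 100 panel entries are unique by miRNA id: when a candidate is already
taken by an earlier contrast, the next-best p-value in the same direction
substitutes, so tier counts are exact. Ties are broken by larger absolute
t-statistic, then lexicographic id. One-vs-one pairs are ordered
alphabetically and "up" means higher in the first class of the pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerEntry",
    "MarkerPanel",
    "ttest_contrast",
    "ovr_contrasts",
    "ovo_contrasts",
    "select_subtype_markers",
    "select_housekeeping",
    "assemble_panel",
    "build_marker_panel",
    "validate_trends",
]

STATS_COLUMNS = ("mirna_id", "contrast", "mean_diff", "t", "p", "direction")


@dataclass(frozen=True)
class MarkerEntry:
    mirna_id: str
    tier: str                    # "ovr" | "ovo" | "housekeeping"
    source_contrast: str | None  # None for housekeeping
    direction: str | None        # "up" | "down"; None for housekeeping


@dataclass
class MarkerPanel:
    entries: list[MarkerEntry]

    def __post_init__(self) -> None:
        ids = [e.mirna_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"panel entries share miRNA ids: {dupes}")
        for e in self.entries:
            if e.tier == "housekeeping" and e.direction is not None:
                raise ValueError(
                    f"housekeeping entry {e.mirna_id} carries a direction")

    def tier_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.tier] = counts.get(e.tier, 0) + 1
        return counts

    @property
    def candidate_ids(self) -> list[str]:
        """The ovr + ovo marker ids (the classification feature set)."""
        return [e.mirna_id for e in self.entries if e.tier != "housekeeping"]

    @property
    def housekeeping_ids(self) -> list[str]:
        return [e.mirna_id for e in self.entries if e.tier == "housekeeping"]

    def candidates(self) -> list[MarkerEntry]:
        return [e for e in self.entries if e.tier != "housekeeping"]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([e.__dict__ for e in self.entries], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            return cls([MarkerEntry(**d) for d in json.load(fh)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def ovr_contrasts(classes: Sequence[str]) -> list[str]:
    return [f"{c}_vs_rest" for c in classes]


def ovo_contrasts(classes: Sequence[str]) -> list[str]:
    cs = sorted(classes)
    return [f"{a}_vs_{b}" for i, a in enumerate(cs) for b in cs[i + 1:]]


def _contrast_groups(labels: pd.Series, contrast):
    """Boolean masks (group of interest, comparison group) for a contrast."""
    if isinstance(contrast, str) and contrast.endswith("_vs_rest"):
        cls = contrast[: -len("_vs_rest")]
        return labels == cls, labels != cls, contrast
    if isinstance(contrast, str) and "_vs_" in contrast:
        a, b = contrast.split("_vs_")
    else:
        a, b = contrast
    return labels == a, labels == b, f"{a}_vs_{b}"


def ttest_contrast(values: pd.DataFrame, labels: pd.Series,
                   contrast, equal_var: bool = True) -> pd.DataFrame:
    """Two-sided two-sample t-test per miRNA for one contrast.

    ``contrast`` is either ``"<class>_vs_rest"`` (or a bare class name) or
    an ordered pair. The mean difference is group-of-interest minus the
    comparison group; direction is "up" iff it is positive.
    """
    if isinstance(contrast, str) and "_vs_" not in contrast:
        contrast = f"{contrast}_vs_rest"
    labels = labels.loc[values.index]
    mask_a, mask_b, name = _contrast_groups(labels, contrast)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"contrast {name}: both groups need >= 2 samples "
            f"(got {int(mask_a.sum())} vs {int(mask_b.sum())})")
    a = values.loc[mask_a.to_numpy()].to_numpy(float)
    b = values.loc[mask_b.to_numpy()].to_numpy(float)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    diff = a.mean(axis=0) - b.mean(axis=0)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.nextafter(0, 1), 1.0)
    t = np.nan_to_num(t, nan=0.0)
    return pd.DataFrame({
        "mirna_id": values.columns,
        "contrast": name,
        "mean_diff": diff,
        "t": t,
        "p": p,
        "direction": np.where(diff > 0, "up", "down"),
    })


def select_subtype_markers(stats_table: pd.DataFrame, k_up: int = 3,
                           k_down: int = 3,
                           exclude: Iterable[str] = (),
                           tier: str = "ovr") -> list[MarkerEntry]:
    """Top-k up/down markers per contrast, unique across contrasts.

    Contrasts are processed in first-appearance order; a miRNA already
    selected (or listed in ``exclude``) is skipped and the next-best
    candidate by (p, -|t|, id) substitutes, so each contrast contributes
    exactly ``k_up + k_down`` entries.
    """
    taken = set(exclude)
    entries: list[MarkerEntry] = []
    for contrast in stats_table["contrast"].drop_duplicates():
        sub = stats_table[stats_table["contrast"] == contrast]
        for direction, k in (("up", k_up), ("down", k_down)):
            cand = sub[sub["direction"] == direction].copy()
            cand["abs_t"] = cand["t"].abs()
            cand = cand.sort_values(
                ["p", "abs_t", "mirna_id"], ascending=[True, False, True])
            picked = 0
            for _, row in cand.iterrows():
                if row["mirna_id"] in taken:
                    continue
                entries.append(MarkerEntry(row["mirna_id"], tier,
                                           contrast, direction))
                taken.add(row["mirna_id"])
                picked += 1
                if picked == k:
                    break
            if picked < k:
                raise ValueError(
                    f"contrast {contrast}: only {picked} unselected "
                    f"{direction}-regulated candidates (need {k})")
    return entries


def select_housekeeping(values: pd.DataFrame, n: int = 10,
                        exclude: Iterable[str] = ()) -> list[str]:
    """The n lowest-variance miRNAs outside the marker tiers (ties by id)."""
    exclude = set(exclude)
    var = values.var(axis=0, ddof=1)
    var = var[[m for m in var.index if m not in exclude]]
    if len(var) < n:
        raise ValueError(
            f"only {len(var)} non-excluded miRNAs; need {n} housekeeping")
    order = sorted(var.index, key=lambda m: (var[m], m))
    return order[:n]


def assemble_panel(ovr: list[MarkerEntry], ovo: list[MarkerEntry],
                   housekeeping: Iterable[str]) -> MarkerPanel:
    hk = [MarkerEntry(m, "housekeeping", None, None) for m in housekeeping]
    return MarkerPanel(list(ovr) + list(ovo) + hk)


def build_marker_panel(values: pd.DataFrame, labels: pd.Series,
                       classes: Sequence[str] | None = None,
                       k_up: int = 3, k_down: int = 3,
                       n_housekeeping: int = 10,
                       ) -> tuple[MarkerPanel, pd.DataFrame]:
    """Full panel construction on normalized discovery values.

    Returns the panel and the concatenated differential-statistics table
    covering every one-vs-rest and one-vs-one contrast.
    """
    if classes is None:
        classes = sorted(labels.loc[values.index].unique())
    ovr_stats = pd.concat(
        [ttest_contrast(values, labels, c) for c in ovr_contrasts(classes)],
        ignore_index=True)
    ovo_stats = pd.concat(
        [ttest_contrast(values, labels, c) for c in ovo_contrasts(classes)],
        ignore_index=True)
    ovr = select_subtype_markers(ovr_stats, k_up, k_down, tier="ovr")
    ovo = select_subtype_markers(
        ovo_stats, k_up, k_down,
        exclude=[e.mirna_id for e in ovr], tier="ovo")
    marker_ids = [e.mirna_id for e in ovr + ovo]
    hk = select_housekeeping(values, n_housekeeping, exclude=marker_ids)
    panel = assemble_panel(ovr, ovo, hk)
    return panel, pd.concat([ovr_stats, ovo_stats], ignore_index=True)


def validate_trends(discovery_stats: pd.DataFrame,
                    validation_stats: pd.DataFrame,
                    panel: MarkerPanel) -> pd.DataFrame:
    """Cross-cohort concordance of each candidate marker's direction.

    A marker validates iff the sign of its mean difference in its source
    contrast strictly matches between cohorts (a zero difference never
    validates). Returns one row per candidate with a ``concordant`` flag;
    the concordant count is the flag sum.
    """
    def lookup(stats_table, mirna, contrast):
        hit = stats_table[(stats_table["mirna_id"] == mirna)
                          & (stats_table["contrast"] == contrast)]
        if hit.empty:
            return None
        return float(hit["mean_diff"].iloc[0])

    rows = []
    for e in panel.candidates():
        d_disc = lookup(discovery_stats, e.mirna_id, e.source_contrast)
        d_val = lookup(validation_stats, e.mirna_id, e.source_contrast)
        if d_disc is None or d_val is None:
            raise ValueError(
                f"contrast {e.source_contrast} for {e.mirna_id} missing from "
                f"{'discovery' if d_disc is None else 'validation'} stats")
        concordant = bool(np.sign(d_disc) == np.sign(d_val) != 0)
        rows.append((e.mirna_id, e.tier, e.source_contrast,
                     d_disc, d_val, concordant))
    return pd.DataFrame(rows, columns=[
        "mirna_id", "tier", "contrast", "discovery_diff", "validation_diff",
        "concordant"])
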