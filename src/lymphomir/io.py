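"""Readers and writers for the pipeline's plain-text table dialects.

Plate tables, expression matrices, and target maps are tab-separated;
pathway collections use the standard GMT layout (set name, description /
source tag, then member genes, tab-separated). All readers validate and
report malformed content with the offending line number; writers produce
files that read back losslessly.
"""

from __future__ import annotations

import pandas as pd

from .quantify import PlateSet, ExpressionMatrix, WELL_COLUMNS

__all__ = [
    "write_plateset", "read_plateset",
    "write_matrix", "read_matrix",
    "write_mask", "read_mask",
    "read_gmt", "write_gmt",
    "read_target_map", "write_target_map",
    "write_annotation", "read_annotation",
]


def write_plateset(plates: PlateSet, path) -> None:
    plates.wells.to_csv(path, sep="\t", index=False, na_rep="")


def read_plateset(path) -> PlateSet:
    df = pd.read_csv(path, sep="\t", dtype={
        "plate_id": str, "well_role": str, "sample_id": str,
        "mirna_id": str, "replicate": int},
        keep_default_na=False, na_values=[""])
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    for col in ("sample_id", "mirna_id"):
        df[col] = df[col].fillna("")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    df["known_copies"] = pd.to_numeric(df["known_copies"], errors="coerce")
    return PlateSet(df)


def write_matrix(values: pd.DataFrame, path) -> None:
    """Samples as rows, miRNAs as columns."""
    values.rename_axis("sample_id").to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate miRNA columns")
    return df


def write_mask(mask: pd.DataFrame, path) -> None:
    mask.astype(int).rename_axis("sample_id").to_csv(path, sep="\t")


def read_mask(path) -> pd.DataFrame:
    return read_matrix(path).astype(bool)


def write_expression(em: ExpressionMatrix, values_path, mask_path) -> None:
    write_matrix(em.values, values_path)
    write_mask(em.mask, mask_path)


def read_expression(values_path, mask_path) -> ExpressionMatrix:
    return ExpressionMatrix(read_matrix(values_path), read_mask(mask_path))


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file into {name: (description/source, gene set)}."""
    pathways: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                    "needs name, description, and at least one gene")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name} has no genes")
            pathways[name] = (desc, set(genes))
    return pathways


def write_gmt(pathways: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in pathways.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_target_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"target map missing column {col!r}")
        empty = df[col].isna() | (df[col].astype(str).str.strip() == "")
        if empty.any():
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"target map line {int(empty.idxmax()) + 2}: empty {col}")
    if df.duplicated(["mirna_id", "gene_id"]).any():
        raise ValueError("target map has duplicate (mirna_id, gene_id) rows")
    return df


def write_target_map(target_map: pd.DataFrame, path) -> None:
    target_map.to_csv(path, sep="\t", index=False)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in annotation")
    return df
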