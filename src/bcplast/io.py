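"""Readers and writers for the pipeline's text formats.

Conventions: expression and centroid matrices are TSV with a gene-id
first column and sample/class ids in the header (genes as rows — a
transposed-looking file is rejected with a hint, never silently
transposed); clinical tables are CSV with ``sample_id,time_months,event``
plus optional covariate columns (event strictly 0/1); gene lists are one
symbol per line; pairings are CSV with ``sample_pre,sample_post``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_list",
    "write_gene_list",
    "read_pairing",
    "write_pairing",
    "read_centroids",
    "write_json",
]

_SAMPLEISH = {"sample", "sample_id", "samples", "sampleid"}


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes × samples TSV matrix.

    Validates: unique gene ids, numeric cells (empty cells become NaN and
    are tolerated — downstream operations exclude them pairwise), and a
    gene-rows orientation (a first header cell like ``sample_id`` trips
    the transposed-input check).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as err:  # ragged rows, encoding...
        raise ValidationError(f"{path}: cannot parse matrix TSV ({err})") from err
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: matrix has no sample columns")
    if (df.index.name or "").strip().lower() in _SAMPLEISH:
        raise ValidationError(
            f"{path}: first column is named {df.index.name!r} — this looks like a "
            "samples-as-rows matrix; transpose it so genes are rows"
        )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValidationError(f"{path}: duplicate gene id(s): {list(dupes[:5])}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"{path}: non-numeric value in column {col!r} at gene {bad[0]!r}"
                )
            df[col] = coerced
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "gene_id")


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical/survival CSV into a sample-indexed DataFrame.

    Requires ``sample_id``, ``time_months`` (positive) and ``event``
    (strictly coded 0/1 — labels like dead/alive are rejected with
    guidance).  Any extra columns are carried along as covariates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:
        raise ValidationError(f"{path}: cannot parse clinical CSV ({err})") from err
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
        raise ValidationError(f"{path}: duplicate sample id(s): {list(dupes[:5])}")
    times = pd.to_numeric(df["time_months"], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        raise ValidationError(f"{path}: time_months must be positive numbers")
    events = pd.to_numeric(df["event"], errors="coerce")
    if events.isna().any() or not set(events.unique()) <= {0, 1}:
        raise ValidationError(
            f"{path}: event must be coded strictly 0 (censored) / 1 (death observed); "
            "recode labels such as dead/alive first"
        )
    df = df.assign(time_months=times.astype(float), event=events.astype(int))
    return df.set_index("sample_id")


def write_clinical_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="sample_id")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ValidationError(f"{path}: empty gene list")
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_pairing(path) -> pd.DataFrame:
    """CSV with ``sample_pre,sample_post`` columns (one pair per row)."""
    df = pd.read_csv(path)
    required = {"sample_pre", "sample_post"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: pairing CSV needs columns {sorted(required)}")
    if df["sample_pre"].duplicated().any() or df["sample_post"].duplicated().any():
        raise ValidationError(f"{path}: pairing must be a bijection (duplicated sample)")
    return df[["sample_pre", "sample_post"]]


def write_pairing(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, index=False)


def read_centroids(path) -> pd.DataFrame:
    """Centroid TSV: gene-id first column, one column per class."""
    df = read_expression_matrix(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: centroid matrix needs at least two classes")
    return df


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
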