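"""Readers and writers for the three tab-delimited study tables.

All files are UTF-8 TSV with "." for missing values.  Floats are written
with 17 significant digits so that write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_COLUMNS,
    METADATA_COLUMNS,
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    LibraryMetadata,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_library_metadata",
    "write_library_metadata",
    "read_gene_annotation",
    "write_gene_annotation",
]

_FLOAT_FMT = "%.17g"
_NA = "."


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a gene x library TPM matrix from TSV.

    First column: gene identifiers; header row: library identifiers; body:
    non-negative numbers.  Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        # float() round-trips the 17-significant-digit representation exactly
        body = df.map(float) if df.size else df.astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in expression matrix {path}: {exc}") from exc
    body.index.name = None
    body.columns.name = None
    return ExpressionMatrix(body)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.validate()
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_library_metadata(path) -> LibraryMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file missing column(s): {', '.join(missing)}")
    df = df[METADATA_COLUMNS].copy()
    for col in ("dpi", "depth_category"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["dpi"] = df["dpi"].astype("Int64").astype(int)
    df["depth_category"] = df["depth_category"].astype("Int64").astype(int)
    return LibraryMetadata(df)


def write_library_metadata(metadata: LibraryMetadata, path) -> None:
    metadata.validate()
    metadata.table[METADATA_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=_NA)


_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no"}


def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v)
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise FormatError(f"cannot parse boolean {col} value {v!r}")

    return series.map(one)


def read_gene_annotation(path, coordinate_convention: str = "zero_half_open") -> GeneAnnotation:
    """Read per-gene annotation from TSV.

    Parameters
    ----------
    coordinate_convention
        ``"zero_half_open"`` (stored as-is) or ``"one_based_inclusive"``
        (genome-browser style; start is decremented by one on input).
    """
    if coordinate_convention not in ("zero_half_open", "one_based_inclusive"):
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA, ""], keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file missing column(s): {', '.join(missing)}")
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str)})
    out["chrom"] = df["chrom"]
    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    if coordinate_convention == "one_based_inclusive":
        start = start - 1
    out["start"] = start
    out["end"] = end
    out["is_r_gene"] = _parse_bool(df["is_r_gene"], "is_r_gene")
    out["is_full_length"] = _parse_bool(df["is_full_length"], "is_full_length")
    if "mir482_target" in df.columns:
        known = df["mir482_target"].notna()
        col = pd.Series(pd.NA, index=df.index, dtype=object)
        col.loc[known] = _parse_bool(df.loc[known, "mir482_target"], "mir482_target")
        out["mir482_target"] = col
    return GeneAnnotation(out)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.validate()
    df = annotation.table.copy()
    for col in ("is_r_gene", "is_full_length", "mir482_target"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: _NA if pd.isna(v) else int(bool(v)))
    for col in ("start", "end"):
        df[col] = df[col].map(lambda v: _NA if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
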