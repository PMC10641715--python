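"""Shared data model: expression matrices, library metadata, gene annotation.

The central container is a gene x library matrix of TPM (transcripts per
million) values together with two side tables: per-library experimental
factors (BioProject, tissue, treatment, ...) and per-gene annotation
(coordinates, R-gene / full-length NBS-LRR flags).  Everything downstream
(expression profiling, ANOSIM, differential expression) consumes a validated
:class:`StudyDataset` bundling the three.

Conventions
-----------
* TPM columns sum to 1e6 (relative tolerance 1e-6) for a matrix flagged as
  TPM-normalized; off-thresholding happens downstream and breaks this.
* Gene coordinates are stored 0-based, half-open.  Readers accept 1-based
  inclusive input behind a flag.
* Missing values are written as "." in TSV files; missing chromosomes mean
  the gene's physical-cluster status is unknowable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "LibraryMetadata",
    "GeneAnnotation",
    "StudyDataset",
    "validate_dataset",
    "TISSUES",
    "TREATMENT_CLASSES",
    "CULTIVAR_STATUSES",
    "SEQ_LAYOUTS",
    "NULL_ORGANISM",
]

#: Category sets for the controlled metadata columns.
TISSUES = frozenset({"root", "stem", "leaf", "fruit", "tuber"})
TREATMENT_CLASSES = frozenset({"mock", "pathogen", "beneficial"})
CULTIVAR_STATUSES = frozenset({"susceptible", "resistant", "beneficial"})
SEQ_LAYOUTS = frozenset({"single", "paired"})
#: Placeholder organism for mock-treated libraries.
NULL_ORGANISM = "none"

METADATA_COLUMNS = [
    "library_id",
    "bioproject",
    "tissue",
    "treatment_class",
    "organism",
    "organism_kingdom",
    "organism_lifecycle",
    "dpi",
    "cultivar_status",
    "seq_layout",
    "depth_category",
]

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "is_r_gene", "is_full_length"]


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates the data model."""


def _check_unique(values, kind: str) -> None:
    counts = pd.Index(values).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise FormatError(f"duplicate {kind} identifier(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Gene x library abundance matrix in TPM units.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and library ids as columns; values
        are non-negative finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.data.shape[1]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "library")
        vals = self.data.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.number):
                raise FormatError("expression matrix contains non-numeric cells")
            if not np.all(np.isfinite(vals)):
                bad = np.argwhere(~np.isfinite(vals))[0]
                raise FormatError(
                    f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                    f"library {self.data.columns[bad[1]]!r}"
                )
            if (vals < 0).any():
                bad = np.argwhere(vals < 0)[0]
                raise FormatError(
                    f"negative value at gene {self.data.index[bad[0]]!r}, "
                    f"library {self.data.columns[bad[1]]!r}"
                )

    def is_tpm_normalized(self, rel_tol: float = 1e-6) -> bool:
        """True when every library column sums to 1e6 within ``rel_tol``."""
        if self.n_genes == 0 or self.n_libraries == 0:
            return False
        sums = self.values.sum(axis=0)
        return bool(np.all(np.abs(sums - 1e6) <= rel_tol * 1e6))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene id(s): {', '.join(map(str, missing))}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)


@dataclass
class LibraryMetadata:
    """Per-library experimental factors (the ANOSIM grouping variables)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def library_ids(self) -> list[str]:
        return list(self.table["library_id"])

    def factor(self, name: str) -> pd.Series:
        """Factor values indexed by library id."""
        if name not in self.table.columns:
            raise KeyError(f"unknown metadata factor {name!r}")
        return self.table.set_index("library_id")[name]

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {', '.join(missing)}")
        _check_unique(self.table["library_id"], "library")
        checks = [
            ("tissue", TISSUES),
            ("treatment_class", TREATMENT_CLASSES),
            ("cultivar_status", CULTIVAR_STATUSES),
            ("seq_layout", SEQ_LAYOUTS),
        ]
        for col, allowed in checks:
            bad = sorted(set(self.table[col]) - set(allowed))
            if bad:
                raise FormatError(f"unknown {col} value(s): {', '.join(map(str, bad))}")
        dpi = pd.to_numeric(self.table["dpi"], errors="coerce")
        if dpi.isna().any() or (dpi < 0).any() or (dpi != dpi.astype(int)).any():
            raise FormatError("dpi must be a non-negative integer")
        depth = pd.to_numeric(self.table["depth_category"], errors="coerce")
        if depth.isna().any() or (~depth.isin([1, 2, 3, 4, 5])).any():
            raise FormatError("depth_category must be an integer in 1..5")
        mock = self.table["treatment_class"] == "mock"
        offenders = self.table.loc[mock & (self.table["organism"] != NULL_ORGANISM), "library_id"]
        if len(offenders):
            raise FormatError(
                "mock-treated libraries must carry the null organism "
                f"({NULL_ORGANISM!r}); offending: {', '.join(offenders)}"
            )


@dataclass
class GeneAnnotation:
    """Per-gene coordinates and R-gene classification flags.

    ``chrom`` is NaN/None for genes whose genomic position is unknown; such
    genes later receive physical-cluster status "unknown".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def r_gene_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_r_gene"], "gene_id"])

    def validate(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing required column(s): {', '.join(missing)}")
        _check_unique(self.table["gene_id"], "gene")
        known = self.table["chrom"].notna()
        sub = self.table.loc[known]
        if len(sub):
            start = pd.to_numeric(sub["start"], errors="coerce")
            end = pd.to_numeric(sub["end"], errors="coerce")
            if start.isna().any() or end.isna().any():
                raise FormatError("genes on a known chromosome need numeric start/end")
            bad = sub.loc[(start >= end), "gene_id"].tolist()
            if bad:
                raise FormatError(
                    "start must be < end (0-based half-open) for gene(s): "
                    + ", ".join(map(str, bad))
                )
        for col in ("is_r_gene", "is_full_length"):
            vals = set(self.table[col].tolist())
            if not vals <= {True, False}:
                raise FormatError(f"{col} must be boolean")


@dataclass
class StudyDataset:
    """A cross-validated bundle of matrix + metadata + annotation."""

    matrix: ExpressionMatrix
    metadata: LibraryMetadata
    annotation: GeneAnnotation

    def r_gene_ids(self) -> list[str]:
        in_matrix = set(self.matrix.gene_ids)
        return [g for g in self.annotation.r_gene_ids() if g in in_matrix]


def validate_dataset(
    matrix: ExpressionMatrix,
    metadata: LibraryMetadata,
    annotation: GeneAnnotation,
    exclude_libraries=None,
) -> StudyDataset:
    """Cross-reference the three components into a :class:`StudyDataset`.

    The metadata must cover exactly the matrix's libraries; the annotation
    must cover all matrix genes (extra annotation rows are permitted).
    ``exclude_libraries`` drops the named libraries from both matrix and
    metadata first — outlier removal is always an explicit list, never
    automatic.
    """
    if exclude_libraries:
        exclude = set(exclude_libraries)
        unknown = sorted(exclude - set(matrix.library_ids))
        if unknown:
            raise FormatError("exclusion list names unknown library id(s): " + ", ".join(unknown))
        keep = [l for l in matrix.library_ids if l not in exclude]
        matrix = ExpressionMatrix(matrix.data[keep])
        metadata = LibraryMetadata(
            metadata.table.loc[metadata.table["library_id"].isin(keep)].reset_index(drop=True)
        )
    mat_libs = set(matrix.library_ids)
    meta_libs = set(metadata.library_ids)
    missing = sorted(mat_libs - meta_libs)
    if missing:
        raise FormatError("metadata missing library id(s): " + ", ".join(missing))
    extra = sorted(meta_libs - mat_libs)
    if extra:
        raise FormatError("metadata has library id(s) absent from matrix: " + ", ".join(extra))
    unannotated = sorted(set(matrix.gene_ids) - set(annotation.gene_ids))
    if unannotated:
        raise FormatError("annotation missing gene id(s): " + ", ".join(unannotated))
    return StudyDataset(matrix=matrix, metadata=metadata, annotation=annotation)
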