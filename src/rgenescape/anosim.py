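"""Analysis of similarities (ANOSIM) from first principles.

The pipeline mirrors the classical recipe for expression matrices: TPM
values are log10(x+1) transformed, pairwise Euclidean distances between
library columns are computed (optionally restricted to a gene subset, e.g.
the R-genes), all N(N-1)/2 distances are ranked with average ranks for
ties, and the statistic

    R = (mean between-group rank - mean within-group rank) / (M / 2)

with M = N(N-1)/2 is compared against its permutation distribution under
random relabelling of the libraries.  R lies in [-1, 1]; large values mean
between-group dissimilarities dominate within-group ones.  Because R is
rank-based it is invariant under any strictly monotone transform of the
distances (so the base of the log transform is immaterial).

The permutation p-value uses the add-one estimator
p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations); when the number of
distinct label assignments is small the full permutation distribution is
enumerated instead and p is exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sympy.utilities.iterables import multiset_permutations

from .datamodel import ExpressionMatrix, LibraryMetadata, StudyDataset

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "log_transform",
    "euclidean_distances",
    "anosim_statistic",
    "anosim_test",
    "factor_screen",
    "n_distinct_assignments",
]

logger = logging.getLogger(__name__)

#: Exhaustive enumeration kicks in at or below this many distinct label
#: assignments.
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities between libraries."""

    library_ids: list[str]
    condensed: np.ndarray  # length N(N-1)/2, scipy condensed order

    def __post_init__(self) -> None:
        n = len(self.library_ids)
        if len(self.condensed) != n * (n - 1) // 2:
            raise ValueError("condensed length does not match library count")
        if (self.condensed < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.library_ids)

    def as_square(self) -> pd.DataFrame:
        return pd.DataFrame(
            squareform(self.condensed), index=self.library_ids, columns=self.library_ids
        )

    def subset(self, keep_idx: np.ndarray) -> "DistanceMatrix":
        sq = squareform(self.condensed)[np.ix_(keep_idx, keep_idx)]
        return DistanceMatrix(
            [self.library_ids[i] for i in keep_idx], squareform(sq, checks=False)
        )


@dataclass
class AnosimResult:
    factor: str
    r: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    exhaustive: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log10(x + 1) transform of every cell."""
    vals = matrix.values
    if (vals < 0).any():
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log10(vals + 1.0), index=matrix.data.index, columns=matrix.data.columns)
    )


def euclidean_distances(matrix: ExpressionMatrix, gene_subset=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between library columns.

    ``gene_subset`` restricts the computation to the named genes (e.g. the
    R-gene repertoire); unknown gene ids are an error.
    """
    if matrix.n_libraries < 2:
        raise ValueError("need at least 2 libraries")
    sub = matrix if gene_subset is None else matrix.subset_genes(list(gene_subset))
    if sub.n_genes == 0:
        raise ValueError("gene subset is empty")
    return DistanceMatrix(matrix.library_ids, pdist(sub.values.T, metric="euclidean"))


def _within_mask(labels: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(len(labels), k=1)
    return labels[iu] == labels[ju]


def _check_groups(labels: np.ndarray, allow_singletons: bool = False) -> dict[str, int]:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if not allow_singletons and (counts < 2).any():
        bad = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError("group(s) with fewer than 2 members: " + ", ".join(bad))
    return {str(u): int(c) for u, c in zip(uniq, counts)}


def _r_from_ranks(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim_statistic(dist: DistanceMatrix, labels) -> float:
    """The ANOSIM R statistic for a fixed grouping."""
    labels = np.asarray(labels)
    if len(labels) != dist.n:
        raise ValueError("labels length must match distance matrix")
    _check_groups(labels)
    ranks = rankdata(dist.condensed)  # average ranks for ties
    return _r_from_ranks(ranks, _within_mask(labels))


def n_distinct_assignments(labels) -> int:
    """Number of distinct label assignments (multinomial coefficient)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def anosim_test(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    factor: str = "group",
    method: str = "auto",
) -> AnosimResult:
    """Permutation test of the ANOSIM R statistic.

    ``method``: "auto" enumerates the full permutation distribution when
    the number of distinct label assignments is at most
    :data:`EXHAUSTIVE_LIMIT`, otherwise samples ``n_permutations`` uniform
    relabellings; "sampled" and "exhaustive" force either path.
    """
    labels = np.asarray(labels)
    if len(labels) != dist.n:
        raise ValueError("labels length must match distance matrix")
    group_sizes = _check_groups(labels)
    ranks = rankdata(dist.condensed)
    iu, ju = np.triu_indices(dist.n, k=1)
    r_obs = _r_from_ranks(ranks, labels[iu] == labels[ju])

    if method not in ("auto", "sampled", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    n_distinct = n_distinct_assignments(labels)
    exhaustive = method == "exhaustive" or (method == "auto" and n_distinct <= EXHAUSTIVE_LIMIT)

    if exhaustive:
        ge = 0
        for perm in multiset_permutations(list(labels)):
            perm = np.asarray(perm)
            r_perm = _r_from_ranks(ranks, perm[iu] == perm[ju])
            if r_perm >= r_obs - 1e-12:
                ge += 1
        p = ge / n_distinct
        return AnosimResult(factor, r_obs, p, n_distinct, group_sizes, exhaustive=True)

    rng = np.random.default_rng(seed)
    ge = 0
    work = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        r_perm = _r_from_ranks(ranks, work[iu] == work[ju])
        if r_perm >= r_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return AnosimResult(factor, r_obs, p, n_permutations, group_sizes, exhaustive=False)


def factor_screen(
    dataset: StudyDataset,
    factors,
    gene_subset=None,
    n_permutations: int = 999,
    seed: int | None = None,
    off_threshold: float | None = None,
    method: str = "sampled",
) -> list[AnosimResult]:
    """One ANOSIM per metadata factor on a shared distance matrix.

    The matrix is log10(x+1) transformed and Euclidean distances are taken
    over ``gene_subset`` (default all genes).  Per factor, libraries with a
    missing value are dropped, groups with a single library are dropped
    with a warning, and factors left with fewer than two usable groups are
    skipped.  Results are sorted by descending R.
    """
    matrix = dataset.matrix
    if off_threshold is not None:
        from .profiling import apply_off_threshold

        matrix = apply_off_threshold(matrix, off_threshold)
    dist = euclidean_distances(log_transform(matrix), gene_subset)
    lib_index = pd.Index(dist.library_ids)

    results: list[AnosimResult] = []
    rng = np.random.default_rng(seed)
    for factor in factors:
        values = dataset.metadata.factor(factor).reindex(lib_index)
        usable = values.notna()
        counts = values[usable].value_counts()
        small = counts[counts < 2].index
        if len(small):
            logger.warning(
                "factor %s: dropping single-library group(s) %s", factor, list(small)
            )
            usable &= ~values.isin(small)
        labels = values[usable].astype(str).to_numpy()
        if len(np.unique(labels)) < 2:
            logger.warning("factor %s skipped: fewer than 2 usable groups", factor)
            continue
        sub = dist.subset(np.flatnonzero(usable.to_numpy()))
        results.append(
            anosim_test(
                sub,
                labels,
                n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
                factor=factor,
                method=method,
            )
        )
    return sorted(results, key=lambda r: -r.r)
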