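"""Descriptive expression profiling: off-thresholding, expression classes,
breadth and core sets, per-library summaries, random-gene-set resampling,
and the gated two-sample test used throughout the comparisons.

The on/off convention follows the TPM < 1 rule: such values are treated as
"off" and set to zero.  Expression classes are six lower-inclusive TPM bins
(off < 1 <= low < 10 <= modest < 50 <= medium < 200 <= high < 1000 <=
very_high).  The "core set" is the genes expressed in strictly more than a
given fraction (default 90%) of libraries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .datamodel import ExpressionMatrix, GeneAnnotation

__all__ = [
    "EXPRESSION_CLASSES",
    "CLASS_EDGES",
    "apply_off_threshold",
    "classify_expression",
    "expression_breadth",
    "core_set",
    "library_summary",
    "random_set_resampling",
    "ResamplingResult",
    "gated_two_sample_test",
    "GatedTestResult",
    "spearman_correlation",
    "CorrelationResult",
    "top_fraction_mean",
    "off_in_A_on_in_B",
]

#: Ordered class labels and their lower bin edges (lower-inclusive).
EXPRESSION_CLASSES = ("off", "low", "modest", "medium", "high", "very_high")
CLASS_EDGES = (0.0, 1.0, 10.0, 50.0, 200.0, 1000.0)


def apply_off_threshold(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Zero out every cell strictly below ``threshold`` (TPM < 1 is "off")."""
    if threshold < 0:
        raise ValueError("off threshold must be non-negative")
    vals = matrix.values.copy()
    vals[vals < threshold] = 0.0
    return ExpressionMatrix(pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns))


def classify_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Assign every cell to one of the six ordered expression classes.

    Returns a gene x library DataFrame of categorical labels.
    """
    idx = np.searchsorted(CLASS_EDGES[1:], matrix.values, side="right")
    labels = np.asarray(EXPRESSION_CLASSES, dtype=object)[idx]
    dtype = pd.CategoricalDtype(categories=list(EXPRESSION_CLASSES), ordered=True)
    df = pd.DataFrame(labels, index=matrix.data.index, columns=matrix.data.columns)
    return df.astype(dtype)


def expression_breadth(matrix: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Per-gene expression breadth and mean abundance.

    breadth
        fraction of libraries with TPM >= threshold.
    mean_expressed
        mean TPM over the libraries where the gene is on (0 if none).
    mean_all
        mean TPM over all libraries.
    """
    if matrix.n_libraries < 1:
        raise ValueError("breadth needs at least one library")
    vals = matrix.values
    on = vals >= threshold
    n_on = on.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_expr = np.where(n_on > 0, (vals * on).sum(axis=1) / np.maximum(n_on, 1), 0.0)
    return pd.DataFrame(
        {
            "breadth": n_on / matrix.n_libraries,
            "mean_expressed": mean_expr,
            "mean_all": vals.mean(axis=1),
        },
        index=matrix.data.index,
    )


def core_set(breadth_table: pd.DataFrame, min_fraction: float = 0.90) -> list[str]:
    """Genes with breadth strictly greater than ``min_fraction``.

    Sorted by descending breadth, ties broken by gene id.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    sel = breadth_table.loc[breadth_table["breadth"] > min_fraction, "breadth"]
    order = sorted(sel.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order]


def library_summary(
    matrix: ExpressionMatrix, annotation: GeneAnnotation, threshold: float = 1.0
) -> pd.DataFrame:
    """Per-library expression summary.

    Columns: n_expressed (genes with TPM >= threshold), n_expressed_r,
    prop_expressed_r (NaN when there are no R-genes), and one count column
    per expression class (class counts sum to the number of genes).
    """
    vals = matrix.values
    on = vals >= threshold
    r_mask = annotation.table.set_index("gene_id")["is_r_gene"].reindex(matrix.gene_ids)
    r_mask = r_mask.fillna(False).to_numpy(dtype=bool)
    n_r = int(r_mask.sum())
    classes = classify_expression(matrix)
    out = pd.DataFrame(index=pd.Index(matrix.library_ids, name="library_id"))
    out["n_expressed"] = on.sum(axis=0)
    out["n_expressed_r"] = on[r_mask].sum(axis=0) if n_r else 0
    out["prop_expressed_r"] = out["n_expressed_r"] / n_r if n_r else np.nan
    for cls in EXPRESSION_CLASSES:
        out[f"n_{cls}"] = (classes == cls).to_numpy().sum(axis=0)
    return out


@dataclass
class ResamplingResult:
    """Random-gene-set resampling outcome.

    ``replicate_means``: library x replicate matrix of per-replicate mean
    TPM.  When ``observed_means`` is present (an R-gene set was supplied),
    ``empirical_quantile`` holds, per library, the fraction of replicate
    means that are <= the observed mean — a two-sided empirical comparison
    of the focal set against random sets of equal size.
    """

    replicate_means: pd.DataFrame
    set_size: int
    expressed_only: bool
    observed_means: pd.Series | None = None
    empirical_quantile: pd.Series | None = None


def random_set_resampling(
    matrix: ExpressionMatrix,
    set_size: int,
    replicates: int = 100,
    expressed_only: bool = True,
    seed: int | None = None,
    observed_gene_ids=None,
    exclude_gene_ids=None,
    threshold: float = 1.0,
) -> ResamplingResult:
    """Compare a focal gene set against random sets of the same size.

    For each library and replicate, ``set_size`` genes are drawn uniformly
    without replacement from the gene pool (all genes by default; pass
    ``exclude_gene_ids`` to remove e.g. the focal R-genes).  The replicate
    statistic is the mean TPM over the sampled genes that are expressed
    (TPM >= threshold) when ``expressed_only``, else over all sampled genes.
    Deterministic given ``seed``.
    """
    pool = [g for g in matrix.gene_ids if not (exclude_gene_ids and g in set(exclude_gene_ids))]
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds gene pool of {len(pool)}")
    if set_size < 1 or replicates < 1:
        raise ValueError("set_size and replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sub = matrix.data.loc[pool].to_numpy()
    n_pool, n_lib = sub.shape

    means = np.zeros((n_lib, replicates))
    for rep in range(replicates):
        for j in range(n_lib):
            pick = rng.choice(n_pool, size=set_size, replace=False)
            vals = sub[pick, j]
            if expressed_only:
                vals = vals[vals >= threshold]
            means[j, rep] = vals.mean() if vals.size else 0.0
    rep_df = pd.DataFrame(
        means, index=pd.Index(matrix.library_ids, name="library_id"),
        columns=[f"rep{r + 1}" for r in range(replicates)],
    )
    observed = quantile = None
    if observed_gene_ids is not None:
        obs = matrix.subset_genes(list(observed_gene_ids)).values
        if expressed_only:
            on = obs >= threshold
            cnt = on.sum(axis=0)
            observed_vals = np.where(cnt > 0, (obs * on).sum(axis=0) / np.maximum(cnt, 1), 0.0)
        else:
            observed_vals = obs.mean(axis=0)
        observed = pd.Series(observed_vals, index=rep_df.index, name="observed_mean")
        quantile = pd.Series(
            (means <= observed_vals[:, None]).mean(axis=1), index=rep_df.index,
            name="empirical_quantile",
        )
    return ResamplingResult(
        replicate_means=rep_df,
        set_size=set_size,
        expressed_only=expressed_only,
        observed_means=observed,
        empirical_quantile=quantile,
    )


@dataclass
class GatedTestResult:
    """Outcome of the normality-gated two-sample location test."""

    test: str                       # "t_test" or "mann_whitney_u"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    variance_p: float | None        # Levene p when the t-branch was taken
    equal_var: bool | None


def _normality_p(x: np.ndarray) -> float:
    # Anderson-Darling for large samples, Shapiro-Wilk otherwise
    if len(x) > 5000:
        return float(normal_ad(np.asarray(x, dtype=float))[1])
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is treated as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def gated_two_sample_test(x, y, alpha_gate: float = 0.05) -> GatedTestResult:
    """Two-sample location test with a normality gate.

    Each sample is tested for normality (Anderson-Darling above 5000
    points, Shapiro-Wilk below).  If both pass at ``alpha_gate``, a
    two-sample t-test is used (pooled when Levene's test does not reject
    equal variances at 0.05, Welch otherwise); otherwise a two-sided
    Mann-Whitney U test (exact for tie-free samples with n <= 8 on both
    sides, normal approximation with tie correction otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 observations")
    px, py = _normality_p(x), _normality_p(y)
    if px > alpha_gate and py > alpha_gate:
        lev_p = float(stats.levene(x, y).pvalue)
        equal_var = lev_p >= 0.05
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        return GatedTestResult(
            test="t_test",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p=(px, py),
            variance_p=lev_p,
            equal_var=equal_var,
        )
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GatedTestResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        normality_p=(px, py),
        variance_p=None,
        equal_var=None,
    )


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Constant input yields a missing (NaN) rho with a warning rather than an
    exception, so batch runs survive degenerate libraries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho is undefined", RuntimeWarning)
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=len(x))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))


def top_fraction_mean(values, fraction: float) -> float:
    """Mean of the ``ceil(fraction * n)`` largest values."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * vals.size)
    return float(np.sort(vals)[-k:].mean())


def off_in_A_on_in_B(
    breadth_a: pd.Series | pd.DataFrame,
    breadth_b: pd.Series | pd.DataFrame,
    min_breadth_b: float = 0.30,
) -> list[str]:
    """Genes silent in condition A but expressed broadly in condition B.

    A gene qualifies when its breadth in A is exactly 0 and its breadth in
    B is strictly greater than ``min_breadth_b``.  Operates on the shared
    gene universe of the two tables; disjoint universes are an error.
    """
    a = breadth_a["breadth"] if isinstance(breadth_a, pd.DataFrame) else breadth_a
    b = breadth_b["breadth"] if isinstance(breadth_b, pd.DataFrame) else breadth_b
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("breadth tables share no genes")
    sel = (a.loc[shared] == 0) & (b.loc[shared] > min_breadth_b)
    return sorted(shared[sel])
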