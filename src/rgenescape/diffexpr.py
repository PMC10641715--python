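"""Differential-expression stand-in between organism-treated and mock
libraries, plus the downstream summary statistics.

Transcript-level count models need per-library quantifier output that a
TPM table no longer carries, so the test here is a deliberately simple,
fully specified gene-level procedure (declared in output metadata as
``welch_log2tpm_v1``): a Welch t-test on log2(TPM + 1) between arms, with
per-arm variances floored at a small constant so that clean separations do
not produce degenerate statistics, Benjamini-Hochberg correction across
all tested genes, and direction calls at FDR <= alpha.  Genes with equal
arm means and zero variance get p = 1 (kept, not dropped, so the BH family
size is stable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneAnnotation, LibraryMetadata
from .profiling import GatedTestResult, gated_two_sample_test

__all__ = [
    "DE_METHOD",
    "DEPair",
    "pair_libraries",
    "de_test",
    "bh_adjust",
    "DESummary",
    "summarize_de",
    "overlap_by_treatment_class",
]

logger = logging.getLogger(__name__)

DE_METHOD = "welch_log2tpm_v1"


@dataclass
class DEPair:
    """One treated-vs-mock contrast within a (bioproject, tissue, dpi) stratum."""

    dataset_id: str
    treated: list[str]
    mock: list[str]
    bioproject: str
    tissue: str
    dpi: int
    treatment_class: str

    def __post_init__(self) -> None:
        if len(self.treated) < 2 or len(self.mock) < 2:
            raise ValueError("both arms need at least 2 replicate libraries")


def pair_libraries(metadata: LibraryMetadata, min_replicates: int = 2) -> list[DEPair]:
    """Build treated-vs-mock contrasts per (bioproject, tissue, dpi) stratum.

    Within a stratum, each non-mock treatment class with >=
    ``min_replicates`` libraries is paired against the mock arm (also
    requiring >= ``min_replicates``).  Incomplete strata are dropped with a
    logged reason; an empty result is allowed.
    """
    tbl = metadata.table
    pairs: list[DEPair] = []
    for (bp, tissue, dpi), grp in tbl.groupby(["bioproject", "tissue", "dpi"], sort=True):
        mock = grp.loc[grp["treatment_class"] == "mock", "library_id"].tolist()
        for tclass, sub in grp.loc[grp["treatment_class"] != "mock"].groupby(
            "treatment_class", sort=True
        ):
            treated = sub["library_id"].tolist()
            if len(mock) < min_replicates or len(treated) < min_replicates:
                logger.info(
                    "stratum (%s, %s, dpi=%s, %s) dropped: %d treated vs %d mock",
                    bp, tissue, dpi, tclass, len(treated), len(mock),
                )
                continue
            pairs.append(
                DEPair(
                    dataset_id=f"{bp}|{tissue}|dpi{dpi}|{tclass}",
                    treated=treated,
                    mock=mock,
                    bioproject=bp,
                    tissue=tissue,
                    dpi=int(dpi),
                    treatment_class=str(tclass),
                )
            )
    return pairs


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (original order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    matrix: ExpressionMatrix,
    pair: DEPair,
    alpha: float = 0.05,
    variance_floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(TPM+1) between the two arms.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (treated
    minus mock), ``p``, ``q`` and ``direction`` in {"up", "down", "ns"};
    the method tag is stored in ``DataFrame.attrs["method"]``.
    """
    for lib in itertools.chain(pair.treated, pair.mock):
        if lib not in matrix.data.columns:
            raise KeyError(f"library {lib!r} not in matrix")
    a = np.log2(matrix.data[pair.treated].to_numpy() + 1.0)
    b = np.log2(matrix.data[pair.mock].to_numpy() + 1.0)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both arms need at least 2 libraries")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = np.maximum(a.var(axis=1, ddof=1), variance_floor)
    v2 = np.maximum(b.var(axis=1, ddof=1), variance_floor)
    log2fc = m1 - m2
    se2 = v1 / n1 + v2 / n2
    t = log2fc / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = (log2fc == 0.0) & (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p[degenerate] = 1.0
    q = bh_adjust(p)
    direction = np.where(q <= alpha, np.where(log2fc > 0, "up", "down"), "ns")
    direction[(q <= alpha) & (log2fc == 0)] = "ns"
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "direction": direction},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    out.attrs["method"] = DE_METHOD
    out.attrs["dataset_id"] = pair.dataset_id
    out.attrs["treatment_class"] = pair.treatment_class
    out.attrs["alpha"] = alpha
    return out


@dataclass
class DESummary:
    """Pooled differential-expression summary across contrasts."""

    n_contrasts: int
    prop_de_r: float
    prop_de_other: float
    prop_up: float          # among DE R-genes
    prop_down: float
    binom_p_up: float       # exact two-sided test of up-fraction = 0.5
    mean_abs_fc_up: float
    mean_abs_fc_down: float
    mean_abs_fc_r: float
    mean_abs_fc_other: float
    fc_up_vs_down: GatedTestResult | None
    fc_r_vs_other: GatedTestResult | None


def _safe_gated(x, y) -> GatedTestResult | None:
    if len(x) < 3 or len(y) < 3:
        return None
    return gated_two_sample_test(x, y)


def summarize_de(de_tables, annotation: GeneAnnotation, alpha: float = 0.05) -> DESummary:
    """Pool DE tables and compute the headline summary statistics.

    Per gene-occurrence (gene x contrast), DE status is q <= alpha.  The
    up/down balance among DE R-genes is tested with an exact two-sided
    binomial test against 0.5; absolute fold-change comparisons use the
    normality-gated two-sample test.
    """
    de_tables = list(de_tables)
    if not de_tables:
        raise ValueError("need at least one DE table")
    is_r = annotation.table.set_index("gene_id")["is_r_gene"]
    rec = []
    for tbl in de_tables:
        r_flags = is_r.reindex(tbl.index).fillna(False).to_numpy(dtype=bool)
        rec.append(
            pd.DataFrame(
                {
                    "is_r": r_flags,
                    "de": (tbl["q"] <= alpha).to_numpy(),
                    "log2fc": tbl["log2fc"].to_numpy(),
                    "direction": tbl["direction"].to_numpy(),
                }
            )
        )
    pooled = pd.concat(rec, ignore_index=True)
    r = pooled[pooled["is_r"]]
    other = pooled[~pooled["is_r"]]
    prop_de_r = float(r["de"].mean()) if len(r) else float("nan")
    prop_de_other = float(other["de"].mean()) if len(other) else float("nan")

    de_r = r[r["de"]]
    n_up = int((de_r["direction"] == "up").sum())
    n_down = int((de_r["direction"] == "down").sum())
    if n_up + n_down:
        prop_up = n_up / (n_up + n_down)
        prop_down = n_down / (n_up + n_down)
        binom_p = float(stats.binomtest(n_up, n_up + n_down, 0.5).pvalue)
    else:
        prop_up = prop_down = binom_p = float("nan")

    abs_up = de_r.loc[de_r["direction"] == "up", "log2fc"].abs().to_numpy()
    abs_down = de_r.loc[de_r["direction"] == "down", "log2fc"].abs().to_numpy()
    de_other = other[other["de"]]
    abs_r = de_r["log2fc"].abs().to_numpy()
    abs_other = de_other["log2fc"].abs().to_numpy()

    def _mean(v):
        return float(np.mean(v)) if len(v) else float("nan")

    return DESummary(
        n_contrasts=len(de_tables),
        prop_de_r=prop_de_r,
        prop_de_other=prop_de_other,
        prop_up=prop_up,
        prop_down=prop_down,
        binom_p_up=binom_p,
        mean_abs_fc_up=_mean(abs_up),
        mean_abs_fc_down=_mean(abs_down),
        mean_abs_fc_r=_mean(abs_r),
        mean_abs_fc_other=_mean(abs_other),
        fc_up_vs_down=_safe_gated(abs_up, abs_down),
        fc_r_vs_other=_safe_gated(abs_r, abs_other),
    )


def overlap_by_treatment_class(de_tables_by_class: dict, alpha: float = 0.05) -> dict:
    """Set algebra of DE genes across treatment classes.

    ``de_tables_by_class`` maps a class name (e.g. "pathogen",
    "beneficial") to an iterable of DE tables.  Returns per-class DE gene
    sets with directions, the genes shared by all classes, and per-class
    exclusive sets.
    """
    gene_dirs: dict[str, dict[str, set]] = {}
    for cls, tables in de_tables_by_class.items():
        dirs: dict[str, set] = {}
        for tbl in tables:
            de = tbl[tbl["q"] <= alpha]
            for gid, direction in zip(de.index, de["direction"]):
                dirs.setdefault(gid, set()).add(direction)
        gene_dirs[cls] = dirs
    sets = {cls: set(d) for cls, d in gene_dirs.items()}
    shared = set.intersection(*sets.values()) if sets else set()
    exclusive = {
        cls: s - set.union(*(o for c, o in sets.items() if c != cls), set())
        if len(sets) > 1
        else set(s)
        for cls, s in sets.items()
    }
    return {
        "by_class": sets,
        "directions": gene_dirs,
        "shared": shared,
        "exclusive": exclusive,
    }
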