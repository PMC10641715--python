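"""Physical clustering of R-genes by the 200-kb window rule.

Two or more R-genes whose start coordinates chain together at <= 200 kb on
the same chromosome (single linkage: consecutive starts, transitively
closed) form a physical cluster.  R-genes without a known chromosome get
status "unknown"; isolated R-genes are "singleton".  Non-R-genes are
ignored entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import GeneAnnotation

__all__ = ["assign_clusters", "cluster_spans"]

DEFAULT_WINDOW_BP = 200_000


def assign_clusters(annotation: GeneAnnotation, window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Partition R-genes into physical clusters.

    Returns one row per R-gene with columns ``gene_id``, ``chrom``,
    ``status`` ("clustered" / "singleton" / "unknown"), ``cluster_id``
    (``chrom:index`` for clusters, NA otherwise) and ``cluster_size``.
    The partition is invariant to the row order of the input, and raising
    ``window_bp`` can only merge clusters, never split them.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    tbl = annotation.table
    r = tbl.loc[tbl["is_r_gene"], ["gene_id", "chrom", "start"]].copy()
    unknown = r["chrom"].isna()
    rows = []
    for gid in r.loc[unknown, "gene_id"]:
        rows.append((gid, pd.NA, "unknown", pd.NA, 0))

    known = r.loc[~unknown].copy()
    known["start"] = known["start"].astype(np.int64)
    # sort by gene_id first so equal-start ties are order-independent
    known = known.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
    for chrom, grp in known.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        new_chain = np.ones(len(grp), dtype=bool)
        new_chain[1:] = np.diff(starts) > window_bp
        chain_ids = np.cumsum(new_chain) - 1
        sizes = np.bincount(chain_ids)
        cluster_index = 0
        chain_to_cluster = {}
        for cid, size in enumerate(sizes):
            if size >= 2:
                cluster_index += 1
                chain_to_cluster[cid] = f"{chrom}:{cluster_index}"
        for gid, cid in zip(grp["gene_id"], chain_ids):
            if cid in chain_to_cluster:
                rows.append((gid, chrom, "clustered", chain_to_cluster[cid], int(sizes[cid])))
            else:
                rows.append((gid, chrom, "singleton", pd.NA, 1))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "status", "cluster_id", "cluster_size"])
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def cluster_spans(annotation: GeneAnnotation, assignment: pd.DataFrame) -> pd.DataFrame:
    """BED-like spans (chrom, start, end, cluster_id, n_genes) of clusters."""
    coords = annotation.table.set_index("gene_id")[["start", "end"]]
    clustered = assignment.loc[assignment["status"] == "clustered"]
    rows = []
    for cid, grp in clustered.groupby("cluster_id", sort=True):
        sub = coords.loc[grp["gene_id"]]
        rows.append(
            (grp["chrom"].iloc[0], int(sub["start"].min()), int(sub["end"].max()), cid, len(grp))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cluster_id", "n_genes"])
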