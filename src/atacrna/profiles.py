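"""Temporal clustering of DEGs and hypergeometric gene-set enrichment.

Clustering operates on row z-scores of log2(FPKM+1), with replicates averaged
per time point first, using agglomerative (Ward) clustering cut at k groups.
Enrichment uses the exact upper-tail hypergeometric test with BH correction
across gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .expression import bh_fdr


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene_id -> cluster 1..k, renumbered by descending size
    k: int
    zscore_matrix: pd.DataFrame  # genes x time points
    degenerate: list[str] = field(default_factory=list)  # constant-profile genes


def timepoint_means(
    fpkm_matrix: pd.DataFrame, meta: pd.DataFrame, order: tuple[str, ...] = ("D0", "D14", "D28")
) -> pd.DataFrame:
    """Average replicate FPKM per time point (columns ordered as given)."""
    cols = {}
    for tp in order:
        samples = list(meta.index[meta["timepoint"] == tp])
        cols[tp] = fpkm_matrix[samples].mean(axis=1)
    return pd.DataFrame(cols)


def row_zscores(mat: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores of log2(x+1); constant rows become all-zero and are
    reported as degenerate."""
    logm = np.log2(mat.to_numpy(dtype=float) + 1.0)
    mu = logm.mean(axis=1, keepdims=True)
    sd = logm.std(axis=1, ddof=0, keepdims=True)
    const = sd[:, 0] < 1e-12
    sd[const] = 1.0
    z = (logm - mu) / sd
    z[const] = 0.0
    degenerate = list(mat.index[const])
    return pd.DataFrame(z, index=mat.index, columns=mat.columns), degenerate


def cluster_degs(
    fpkm_by_timepoint: pd.DataFrame,
    degs: list[str],
    k: int = 6,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Hierarchical clustering of DEG temporal profiles into k clusters.

    Profiles are row z-scores of log2(FPKM+1) over per-time-point means;
    the Ward/Euclidean tree is cut at k and labels are renumbered by
    descending cluster size (cluster 1 largest), ties broken by the smallest
    original label for determinism.
    """
    if k > len(degs):
        raise ValueError(f"k={k} exceeds number of genes ({len(degs)})")
    mat = fpkm_by_timepoint.loc[degs]
    z, degenerate = row_zscores(mat)
    link = hierarchy.linkage(z.to_numpy(), method=method, metric=metric)
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=z.index, name="cluster")
    return ClusterAssignment(labels=labels, k=k, zscore_matrix=z, degenerate=degenerate)


def hypergeom_tail(x: int, K: int, n: int, M: int) -> float:
    """Exact upper tail P(X >= x) for X ~ Hypergeometric(M, K, n).

    M is the population size, K the number of marked items, n the draw size
    and x the observed number of marked draws.
    """
    if not (0 <= x <= n <= M and 0 <= K <= M):
        raise ValueError(f"impossible hypergeometric arguments x={x} K={K} n={n} M={M}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, M, K, n))


def enrich_gene_sets(
    cluster_genes: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a cluster.

    Sets are restricted to the universe; only sets with overlap >= 1 are
    reported. BH correction is applied across the reported sets. Returns a
    table sorted by q then set name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    clust = set(cluster_genes) & uni
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & uni
        overlap = len(clust & members)
        if overlap < 1:
            continue
        p = hypergeom_tail(overlap, len(members), len(clust), len(uni))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "cluster_size": len(clust),
                "universe_size": len(uni),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "cluster_size", "universe_size", "p"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_threshold
        out = out.sort_values(["q", "set_name"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
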