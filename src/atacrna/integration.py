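"""Joint accessibility-expression analyses.

Correlates fold-changes of differential accessibility with differential
expression over annotated gene-peak pairs, builds per-OCR signal matrices
over center +/- 5 kb windows with k-means row grouping, and computes
strand-oriented per-cluster TSS metaprofiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .atac import ConsensusPeak
from .io import GeneModel

logger = logging.getLogger(__name__)

#: annotation categories admitted to the FC-FC correlation
FCFC_CATEGORIES = ("promoter-TSS", "exon", "intron")


@dataclass
class FcFcResult:
    r: float
    p: float
    n: int
    records: pd.DataFrame


def fcfc_correlation(
    expr_de: pd.DataFrame,
    access_de: pd.DataFrame,
    peaks: list[ConsensusPeak],
    p_threshold: float = 0.05,
    best_peak_per_gene: bool = False,
) -> FcFcResult:
    """Pearson correlation between accessibility and expression log2FC.

    Peaks annotated promoter-TSS/exon/intron with accessibility p <
    ``p_threshold`` are joined to their nearest gene's expression result;
    each qualifying (gene, peak) pair contributes one point, unless
    ``best_peak_per_gene`` keeps only the peak with max |accessibility FC|
    per gene.
    """
    acc = access_de.set_index("peak_id")
    expr = expr_de.set_index("gene_id")
    rows = []
    for pk in peaks:
        if pk.category not in FCFC_CATEGORIES or pk.nearest_gene is None:
            continue
        pid = pk.peak_id
        if pid not in acc.index or pk.nearest_gene not in expr.index:
            continue
        arec = acc.loc[pid]
        if not (arec["p"] < p_threshold):
            continue
        rows.append(
            {
                "gene_id": pk.nearest_gene,
                "peak_id": pid,
                "category": pk.category,
                "expr_log2fc": float(expr.loc[pk.nearest_gene, "log2fc"]),
                "access_log2fc": float(arec["log2fc"]),
            }
        )
    records = pd.DataFrame(
        rows, columns=["gene_id", "peak_id", "category", "expr_log2fc", "access_log2fc"]
    )
    if best_peak_per_gene and len(records):
        records = (
            records.assign(absfc=records["access_log2fc"].abs())
            .sort_values(["absfc", "peak_id"], ascending=[False, True], kind="stable")
            .groupby("gene_id", as_index=False)
            .first()
            .drop(columns="absfc")
        )
    if len(records) < 3:
        raise ValueError(f"only {len(records)} gene-peak pairs; need >= 3")
    r, p = stats.pearsonr(records["expr_log2fc"], records["access_log2fc"])
    return FcFcResult(r=float(r), p=float(p), n=len(records), records=records)


@dataclass
class SignalMatrix:
    values: pd.DataFrame  # OCRs x position bins, per-million scaled
    bin_width: int
    half_window: int
    row_cluster: pd.Series | None = None


def signal_matrix(
    fragments: pd.DataFrame,
    ocrs: list[ConsensusPeak],
    half_window: int = 5000,
    bin_width: int = 100,
    sample: str | None = None,
) -> SignalMatrix:
    """Per-OCR fragment-midpoint coverage over center +/- half_window.

    Values are counts per bin scaled per million fragments of the (selected)
    sample, so doubling library size leaves them unchanged. Bin membership is
    by fragment midpoint.
    """
    frags = fragments if sample is None else fragments[fragments["sample"] == sample]
    total = len(frags)
    n_bins = (2 * half_window) // bin_width
    mat = np.zeros((len(ocrs), n_bins))
    mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
    chroms = frags["chrom"].to_numpy()
    order = np.argsort(mids, kind="stable")
    mids_s, chroms_s = mids[order], chroms[order]
    for i, pk in enumerate(ocrs):
        center = pk.interval.midpoint
        lo, hi = center - half_window, center + half_window
        j0, j1 = np.searchsorted(mids_s, [lo, hi])
        sel = slice(j0, j1)
        same = chroms_s[sel] == pk.interval.chrom
        pos = mids_s[sel][same]
        bins = ((pos - lo) // bin_width).astype(int)
        np.add.at(mat[i], np.clip(bins, 0, n_bins - 1), 1.0)
    scale = 1e6 / total if total else 0.0
    cols = [int(-half_window + (b + 0.5) * bin_width) for b in range(n_bins)]
    values = pd.DataFrame(mat * scale, index=[p.peak_id for p in ocrs], columns=cols)
    return SignalMatrix(values=values, bin_width=bin_width, half_window=half_window)


def kmeans_rows(matrix: pd.DataFrame, k: int, seed: int = 0) -> pd.Series:
    """k-means row labels (k-means++ init, 10 restarts, best inertia)."""
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of rows ({len(matrix)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy())
    return pd.Series(labels, index=matrix.index, name="row_cluster")


def promoter_metaprofile(
    fragments: pd.DataFrame,
    genes: list[GeneModel],
    cluster_assignment: pd.Series,
    half_window: int = 5000,
    bin_width: int = 100,
) -> dict[tuple[int, str], np.ndarray]:
    """Mean per-million TSS coverage per (expression cluster, sample).

    Profiles are strand-oriented: upstream of the TSS maps to the left half
    regardless of gene strand. Empty clusters give zero profiles (with a
    warning).
    """
    n_bins = (2 * half_window) // bin_width
    samples = sorted(fragments["sample"].unique())
    gene_by_id = {g.gene_id: g for g in genes}
    out: dict[tuple[int, str], np.ndarray] = {}
    for sample in samples:
        frags = fragments[fragments["sample"] == sample]
        total = len(frags)
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        chroms = frags["chrom"].to_numpy()
        order = np.argsort(mids, kind="stable")
        mids_s, chroms_s = mids[order], chroms[order]
        for cluster in sorted(cluster_assignment.unique()):
            members = [
                gene_by_id[g]
                for g in cluster_assignment.index[cluster_assignment == cluster]
                if g in gene_by_id
            ]
            prof = np.zeros(n_bins)
            if not members:
                logger.warning("metaprofile: cluster %s empty", cluster)
                out[(int(cluster), sample)] = prof
                continue
            for g in members:
                lo, hi = g.tss - half_window, g.tss + half_window
                j0, j1 = np.searchsorted(mids_s, [lo, hi])
                same = chroms_s[j0:j1] == g.chrom
                pos = mids_s[j0:j1][same]
                bins = np.clip(((pos - lo) // bin_width).astype(int), 0, n_bins - 1)
                if g.strand == "-":
                    bins = n_bins - 1 - bins
                np.add.at(prof, bins, 1.0)
            scale = 1e6 / total if total else 0.0
            out[(int(cluster), sample)] = prof * scale / len(members)
    return out
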