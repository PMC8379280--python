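"""lncRNA-focused statistics.

Three questions about the non-coding side of a differential-expression time
course: are lncRNAs over-represented among the top-ranked DEGs (by absolute
fold-change), which lncRNA classes are enriched among DE lncRNAs, and do DE
lncRNAs co-express with their annotated protein-coding targets?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, LNCRNA_BIOTYPES
from .profiles import hypergeom_tail


@dataclass
class TopNTest:
    comparison: str
    N: int
    n_lnc: int
    n_coding: int
    p_lnc: float
    p_coding: float

    @property
    def lnc_more_significant(self) -> bool:
        return self.p_lnc < self.p_coding


def rank_degs_by_fc(de_table: pd.DataFrame) -> pd.DataFrame:
    """DEGs of one comparison ranked by |linear FC| descending; ties broken
    by smaller q, then lexicographic gene id (deterministic)."""
    degs = de_table[de_table["is_deg"]].copy()
    degs["abs_fc"] = 2.0 ** np.abs(degs["log2fc"])
    return degs.sort_values(
        ["abs_fc", "q", "gene_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def topn_biotype_test(de_table: pd.DataFrame, N: int) -> TopNTest:
    """Hypergeometric test for biotype composition of the top-N ranked DEGs.

    The population is all DEGs of the comparison (M), the marked items are DE
    lncRNAs (resp. coding genes, K), the draw is the top N by |FC| and x the
    observed biotype count in the top N; p is the exact upper tail.
    """
    ranked = rank_degs_by_fc(de_table)
    M = len(ranked)
    if N > M:
        N = M
    is_lnc = ranked["biotype"].isin(LNCRNA_BIOTYPES).to_numpy()
    K_lnc = int(is_lnc.sum())
    K_cod = M - K_lnc
    top = is_lnc[:N]
    x_lnc = int(top.sum())
    x_cod = N - x_lnc
    return TopNTest(
        comparison=str(de_table["comparison"].iloc[0]) if len(de_table) else "",
        N=N,
        n_lnc=x_lnc,
        n_coding=x_cod,
        p_lnc=hypergeom_tail(x_lnc, K_lnc, N, M),
        p_coding=hypergeom_tail(x_cod, K_cod, N, M),
    )


def lnc_class_enrichment(
    de_lncrnas: list[str], genes: list[GeneModel]
) -> pd.DataFrame:
    """Per-class hypergeometric enrichment of DE lncRNAs over the annotation.

    Population M = all annotated lncRNAs, marked K = those of the class,
    draw n = DE lncRNAs, x = DE lncRNAs of the class.
    """
    ann_lnc = {g.gene_id: g.biotype for g in genes if g.is_lncrna}
    de_set = [g for g in de_lncrnas if g in ann_lnc]
    M, n = len(ann_lnc), len(de_set)
    rows = []
    for cls in sorted(LNCRNA_BIOTYPES):
        K = sum(1 for b in ann_lnc.values() if b == cls)
        if K == 0:
            continue  # class absent from annotation
        x = sum(1 for g in de_set if ann_lnc[g] == cls)
        rows.append(
            {"class": cls, "K": K, "x": x, "n": n, "M": M,
             "p": hypergeom_tail(x, K, n, M) if n else 1.0}
        )
    return pd.DataFrame(rows, columns=["class", "K", "x", "n", "M", "p"])


@dataclass
class PairCorrelation:
    lncrna_id: str
    target_id: str
    r: float
    p: float
    direction: str  # positive | negative | undefined
    both_de: bool = False


def lnc_target_correlation(
    log_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> tuple[list[PairCorrelation], dict]:
    """Pearson co-expression of lncRNA-target pairs across all samples.

    ``log_expr`` is the log2(FPKM+1) genes x samples matrix over every sample
    of every time point. Constant series make r undefined; the pair is kept
    but flagged. The summary reports the number of pairs, how many reach
    p < alpha, and the positive fraction among those significant.
    """
    out: list[PairCorrelation] = []
    for lnc, tgt in pairs:
        if lnc not in log_expr.index or tgt not in log_expr.index:
            continue
        x = log_expr.loc[lnc].to_numpy(dtype=float)
        y = log_expr.loc[tgt].to_numpy(dtype=float)
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            out.append(PairCorrelation(lnc, tgt, np.nan, np.nan, "undefined"))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(
            PairCorrelation(lnc, tgt, float(r), float(p),
                            "positive" if r >= 0 else "negative")
        )
    sig = [pc for pc in out if np.isfinite(pc.p) and pc.p < alpha]
    pos = [pc for pc in sig if pc.direction == "positive"]
    summary = {
        "n_pairs": len(out),
        "n_significant": len(sig),
        "frac_significant": len(sig) / len(out) if out else np.nan,
        "n_positive_significant": len(pos),
        "frac_positive_of_significant": len(pos) / len(sig) if sig else np.nan,
    }
    return out, summary


def fc_concordance(
    pairs: list[tuple[str, str]], de_table: pd.DataFrame
) -> pd.DataFrame:
    """Classify each lncRNA-target pair by fold-change direction agreement
    within one comparison: both_up, both_down, or discordant; ``both_de``
    is set when both members pass the DEG rule."""
    idx = de_table.set_index("gene_id")
    rows = []
    for lnc, tgt in pairs:
        if lnc not in idx.index or tgt not in idx.index:
            continue
        fl, ft = float(idx.loc[lnc, "log2fc"]), float(idx.loc[tgt, "log2fc"])
        if fl > 0 and ft > 0:
            cls = "both_up"
        elif fl < 0 and ft < 0:
            cls = "both_down"
        else:
            cls = "discordant"
        rows.append(
            {
                "lncrna_id": lnc,
                "target_id": tgt,
                "lnc_log2fc": fl,
                "target_log2fc": ft,
                "classification": cls,
                "both_de": bool(idx.loc[lnc, "is_deg"]) and bool(idx.loc[tgt, "is_deg"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "target_id", "lnc_log2fc", "target_log2fc",
                 "classification", "both_de"],
    )


def percent_positive(n_positive: int, n_significant: int) -> int:
    """Positive share of significant correlations as an integer percent."""
    if n_significant == 0:
        raise ValueError("no significant correlations")
    return round(100.0 * n_positive / n_significant)


def percent_of(numerator: int, denominator: int) -> int:
    """Integer-percent helper used in reporting (e.g. significant share of
    curated pairs, TF share of DE coding genes is reported at 0.1 precision
    via :func:`percent_of1`)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator)


def percent_of1(numerator: int, denominator: int) -> float:
    """Percentage at one decimal place."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, 1)
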