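"""PWM motif scanning with exact p-values and downstream motif statistics.

Scanning scores every position of every sequence on both strands with the
log-odds matrix of each PWM, converts scores to exact p-values via a
dynamic-programming convolution of the per-position score distributions
under a 0-order background model, applies BH across all scanned positions
per motif, and keeps hits with q below a threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .expression import bh_fdr
from .io import PWM

#: pseudo-probability floor for log-odds entries
EPS = 1e-4
#: score discretisation grid, in bits
SCORE_GRID = 1e-3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifHit:
    motif_id: str
    sequence_id: str
    offset: int  # 0-based on the forward sequence
    strand: str
    score: float  # log2 odds
    p: float
    q: float = np.nan


def log_odds(pwm: PWM, background: np.ndarray | None = None) -> np.ndarray:
    """L x 4 log2 probability/background matrix with an epsilon floor keeping
    entries finite at probability zero."""
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    return np.log2((pwm.probs + EPS) / (bg[None, :] + EPS))


def _score_ints(pwm: PWM, background: np.ndarray | None = None) -> np.ndarray:
    return np.round(log_odds(pwm, background) / SCORE_GRID).astype(np.int64)


def score_distribution(
    pwm: PWM, background: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Exact distribution of the discretised word score under the background.

    Returns (tail, min_int) where ``tail[i]`` = P(score >= (min_int + i) *
    grid) for a random background word of the motif's length.
    """
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    ints = _score_ints(pwm, background)
    dist = np.array([1.0])
    cur_min = 0
    for i in range(len(pwm)):
        row = ints[i]
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + hi - lo)
        for b in range(4):
            off = int(row[b]) - lo
            new[off : off + len(dist)] += dist * bg[b]
        dist = new
        cur_min += lo
    tail = np.cumsum(dist[::-1])[::-1]
    return tail, cur_min


def score_pvalue(pwm: PWM, score: float, background: np.ndarray | None = None) -> float:
    """Exact P(word score >= score) under the background model, on the
    discretisation grid. Scores above the maximum achievable return the
    smallest positive grid mass."""
    tail, min_int = score_distribution(pwm, background)
    idx = int(np.round(score / SCORE_GRID)) - min_int
    if idx < 0:
        return 1.0
    if idx >= len(tail):
        positive = tail[tail > 0]
        return float(positive[-1]) if len(positive) else float(tail[-1])
    return float(min(tail[idx], 1.0))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def estimate_background(sequences: dict[str, str]) -> np.ndarray:
    """0-order ACGT frequencies over the scanned set (both strands, so the
    estimate is strand-symmetrised); N is ignored."""
    counts = np.zeros(4)
    for seq in sequences.values():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            counts[i] += np.count_nonzero(arr == b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    fwd = counts / counts.sum()
    return (fwd + fwd[::-1]) / 2.0  # A<->T, C<->G symmetry


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, idx in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = idx
    return out


def scan(
    pwms: list[PWM],
    sequences: dict[str, str],
    q_threshold: float = 0.1,
    background: np.ndarray | None = None,
    pool: str = "motif",
) -> list[MotifHit]:
    """Scan sequences with PWMs on both strands; retain hits with q < 0.1.

    Positions containing N contribute zero score. With ``pool="motif"``
    (default, most conservative) q-values come from BH over all positions x
    sequences x strands per motif; ``pool="sequence"`` applies BH within
    each sequence instead. Background defaults to the 0-order composition
    of the scanned set.
    """
    if pool not in ("motif", "sequence"):
        raise ValueError(f"unknown BH pooling {pool!r}")
    if background is None:
        background = estimate_background(sequences)
    ids = sorted(sequences)
    hits: list[MotifHit] = []
    encoded_fwd = {sid: _encode(sequences[sid]) for sid in ids}
    encoded_rev = {sid: _encode(reverse_complement(sequences[sid])) for sid in ids}

    for pwm in pwms:
        L = len(pwm)
        lo = log_odds(pwm, background)
        ints = np.round(lo / SCORE_GRID).astype(np.int64)
        ints5 = np.hstack([ints, np.zeros((L, 1), dtype=np.int64)])  # N -> 0
        tail, min_int = score_distribution(pwm, background)

        raw: list[tuple[str, int, str, int]] = []  # sid, offset, strand, int score
        for sid in ids:
            for strand, enc in (("+", encoded_fwd[sid]), ("-", encoded_rev[sid])):
                S = len(enc)
                if S < L:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(enc, L)
                scores = ints5[np.arange(L)[None, :], win].sum(axis=1)
                for pos in range(len(scores)):
                    off = pos if strand == "+" else S - L - pos
                    raw.append((sid, off, strand, int(scores[pos])))
        if not raw:
            continue
        score_ints = np.array([r[3] for r in raw])
        idx = np.clip(score_ints - min_int, 0, len(tail) - 1)
        pvals = tail[idx]
        pvals[score_ints - min_int < 0] = 1.0
        if pool == "motif":
            qvals = bh_fdr(pvals)
        else:
            qvals = np.empty_like(pvals)
            sids = np.array([r[0] for r in raw])
            for sid in np.unique(sids):
                mask = sids == sid
                qvals[mask] = bh_fdr(pvals[mask])
        keep = qvals < q_threshold
        for j in np.nonzero(keep)[0]:
            sid, off, strand, si = raw[j]
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    sequence_id=sid,
                    offset=off,
                    strand=strand,
                    score=si * SCORE_GRID,
                    p=float(pvals[j]),
                    q=float(qvals[j]),
                )
            )
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": h.motif_id,
                "sequence_id": h.sequence_id,
                "offset": h.offset,
                "strand": h.strand,
                "score": h.score,
                "p": h.p,
                "q": h.q,
            }
            for h in hits
        ],
        columns=["motif_id", "sequence_id", "offset", "strand", "score", "p", "q"],
    )


# ---------------------------------------------------------------------------
# motif frequency matrices


def cluster_motif_matrix(
    hits: list[MotifHit],
    clusters: pd.Series,
    tf_of_motif: dict[str, str],
    tf_max_fpkm: pd.Series | None = None,
    fpkm_min: float = 1.0,
    mad_min: float = 0.05,
) -> pd.DataFrame:
    """TF x expression-cluster matrix of promoter motif frequencies.

    Values are the percent of genes in each cluster whose promoter carries at
    least one retained hit of any motif of the TF. TFs not expressed
    (max FPKM < ``fpkm_min``, when expression is supplied) or with constant
    frequencies across clusters (median absolute deviation of the fraction
    < ``mad_min``) are dropped. Rows are ordered by hierarchical clustering
    (average linkage) when there are >= 3 TFs.
    """
    cluster_ids = sorted(clusters.unique())
    genes_by_cluster = {c: set(clusters.index[clusters == c]) for c in cluster_ids}
    genes_with_hit: dict[str, set[str]] = {}
    for h in hits:
        tf = tf_of_motif.get(h.motif_id, h.motif_id)
        genes_with_hit.setdefault(tf, set()).add(h.sequence_id)

    rows = {}
    for tf in sorted(genes_with_hit):
        if tf_max_fpkm is not None:
            if tf not in tf_max_fpkm.index or tf_max_fpkm[tf] < fpkm_min:
                continue
        vals = []
        for c in cluster_ids:
            members = genes_by_cluster[c]
            frac = len(genes_with_hit[tf] & members) / len(members) if members else 0.0
            vals.append(100.0 * frac)
        arr = np.array(vals)
        mad = float(np.median(np.abs(arr / 100.0 - np.median(arr / 100.0))))
        if mad < mad_min:
            continue
        rows[tf] = arr
    mat = pd.DataFrame(rows, index=[f"cluster_{c}" for c in cluster_ids]).T
    if len(mat) >= 3:
        link = hierarchy.linkage(mat.to_numpy(), method="average")
        order = hierarchy.leaves_list(link)
        mat = mat.iloc[order]
    return mat


ENHANCER_CATEGORIES = frozenset({"intergenic", "intron", "exon", "3UTR", "5UTR"})


def promoter_enhancer_frequency(
    hits: list[MotifHit],
    peak_categories: pd.Series,
    tf_of_motif: dict[str, str],
    de_tfs: set[str] | None = None,
    include: set[str] = frozenset(),
) -> pd.DataFrame:
    """Per-TF motif frequency in promoter-class vs enhancer-class peaks.

    Frequency = percent of peaks of the class containing >= 1 retained hit of
    the motif. Per TF the single most enriched motif — the one maximising
    freq_promoter + freq_enhancer — is reported. When ``de_tfs`` is given the
    output is restricted to those TFs plus any named in ``include``.
    """
    promoter_peaks = set(peak_categories.index[peak_categories == "promoter-TSS"])
    enhancer_peaks = set(
        peak_categories.index[peak_categories.isin(ENHANCER_CATEGORIES)]
    )
    peaks_with_hit: dict[str, set[str]] = {}
    for h in hits:
        peaks_with_hit.setdefault(h.motif_id, set()).add(h.sequence_id)

    per_motif = []
    for motif_id in sorted(set(tf_of_motif) | set(peaks_with_hit)):
        hit_peaks = peaks_with_hit.get(motif_id, set())
        fp = 100.0 * len(hit_peaks & promoter_peaks) / len(promoter_peaks) if promoter_peaks else 0.0
        fe = 100.0 * len(hit_peaks & enhancer_peaks) / len(enhancer_peaks) if enhancer_peaks else 0.0
        per_motif.append(
            {"motif_id": motif_id, "tf": tf_of_motif.get(motif_id, motif_id),
             "freq_promoter": fp, "freq_enhancer": fe}
        )
    df = pd.DataFrame(per_motif)
    if df.empty:
        return df
    df["total"] = df["freq_promoter"] + df["freq_enhancer"]
    best = (
        df.sort_values(["total", "motif_id"], ascending=[False, True], kind="stable")
        .groupby("tf", as_index=False)
        .first()
    )
    if de_tfs is not None:
        keep = best["tf"].isin(set(de_tfs) | set(include))
        best = best[keep]
    return best.drop(columns="total").reset_index(drop=True)


def tf_deg_correlation(
    tf_expression: pd.DataFrame,
    deg_expression: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each TF with each DEG across all samples.

    BH correction is applied per TF across DEGs. Returns (records, summary);
    the summary gives per-TF percentages of DEGs with significant positive
    and negative correlation.
    """
    from scipy import stats

    samples = [c for c in tf_expression.columns if c in deg_expression.columns]
    n = len(samples)
    if n < 3:
        raise ValueError("need >= 3 shared samples")
    X = tf_expression[samples].to_numpy(dtype=float)
    Y = deg_expression[samples].to_numpy(dtype=float)

    def standardize(m: np.ndarray) -> np.ndarray:
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, ddof=0, keepdims=True)
        sd[sd < 1e-12] = np.nan
        return (m - mu) / sd

    R = standardize(X) @ standardize(Y).T / n
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    P[np.isclose(np.abs(R), 1.0)] = 0.0

    records = []
    summary = []
    for i, tf in enumerate(tf_expression.index):
        q = bh_fdr(P[i])
        sig = q < fdr_threshold
        for j, gene in enumerate(deg_expression.index):
            records.append(
                {"tf": tf, "gene_id": gene, "r": R[i, j], "p": P[i, j], "q": q[j]}
            )
        n_deg = len(deg_expression)
        summary.append(
            {
                "tf": tf,
                "pct_positive": 100.0 * np.sum(sig & (R[i] > 0)) / n_deg,
                "pct_negative": 100.0 * np.sum(sig & (R[i] < 0)) / n_deg,
            }
        )
    return pd.DataFrame(records), pd.DataFrame(summary)
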