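"""Fragment- and peak-level ATAC-Seq computations.

Covers the transposase (Tn5) insertion-site offset, fragment-size
histograms with nucleosome-mode detection, consensus open-chromatin-region
(OCR) construction by gap-bounded merging, time-point Venn categories,
genomic annotation with a promoter-first priority, differential
accessibility, interval-overlap statistics and locus-level Mann-Whitney
tests.

Fragments are pandas DataFrames with columns ``chrom, start, end, sample``
and optionally ``strand`` (strand of the generating read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import signal, stats

from .expression import nb_test
from .io import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

TIMEPOINTS = ("D0", "D14", "D28")

#: promoter-TSS definition: 1 kb upstream plus 100 bp downstream of the TSS
PROMOTER_UP = 1000
PROMOTER_DOWN = 100
#: merge gap for consensus peaks ("within 100 bp", inclusive)
MERGE_GAP = 100

CATEGORY_PRIORITY = ("promoter-TSS", "TTS", "5UTR", "3UTR", "exon", "intron", "intergenic")


@dataclass
class ConsensusPeak:
    interval: GenomicInterval
    present_in: set[str]
    category: str | None = None
    nearest_gene: str | None = None
    dist_to_tss: int | None = None
    counts: dict = field(default_factory=dict)

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    @property
    def specific_to(self) -> str | None:
        """The single time point this peak is specific to, if any."""
        return next(iter(self.present_in)) if len(self.present_in) == 1 else None


@dataclass
class FragmentSizeHistogram:
    bin_width: int
    bin_centers: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    modes: list[float]  # bp positions of detected local maxima, ascending


# ---------------------------------------------------------------------------
# fragments


def tn5_shift(fragments: pd.DataFrame) -> pd.DataFrame:
    """Offset read cut sites to transposase insertion centers: +4 on the plus
    strand, -5 on the minus strand.

    For a paired-end fragment the plus-strand cut is the start and the
    minus-strand cut the end, so ``start += 4`` and ``end -= 5``. Records
    without strand are left unshifted with a warning. Re-applying to an
    already-shifted table raises.
    """
    if fragments.attrs.get("tn5_shifted"):
        raise ValueError("fragments already Tn5-shifted; refusing to shift twice")
    out = fragments.copy()
    if "strand" in out.columns:
        has = out["strand"].isin(["+", "-"])
        if (~has).any():
            logger.warning("tn5_shift: %d records without strand left unshifted",
                           int((~has).sum()))
        plus = out["strand"] == "+"
        minus = out["strand"] == "-"
        out.loc[plus, "start"] += 4
        out.loc[minus, "end"] -= 5
    else:
        out["start"] += 4
        out["end"] -= 5
    out.attrs["tn5_shifted"] = True
    return out


def size_histogram(fragments: pd.DataFrame, bin_width: int = 10) -> FragmentSizeHistogram:
    """Fragment-size histogram with smoothed local-maxima mode detection.

    Bins of ``bin_width`` bp from zero; the histogram is smoothed with a
    3-bin moving average and modes are local maxima with prominence at least
    5% of the smoothed maximum. Mode positions are bin centers.
    """
    sizes = (fragments["end"] - fragments["start"]).to_numpy()
    hi = int(np.ceil(sizes.max() / bin_width)) * bin_width + bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, _ = np.histogram(sizes, bins=edges)
    smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    prominence = 0.05 * smoothed.max()
    peaks, _ = signal.find_peaks(smoothed, prominence=prominence)
    centers = edges[:-1] + bin_width / 2.0
    modes = sorted(float(centers[i]) for i in peaks)
    return FragmentSizeHistogram(bin_width, centers, counts, smoothed, modes)


def round_to(x: float, nearest: int = 10) -> int:
    return int(round(x / nearest) * nearest)


def nucleosome_modes(hist: FragmentSizeHistogram, min_bp: float = 150) -> list[int]:
    """Detected modes at or above ``min_bp``, rounded to the nearest 10 bp.
    The first is the mononucleosome mode, the second the dinucleosome."""
    return [round_to(m, 10) for m in hist.modes if m >= min_bp]


# ---------------------------------------------------------------------------
# consensus peaks


def merge_consensus(
    peak_sets: dict[str, list[GenomicInterval]], gap: int = MERGE_GAP
) -> list[ConsensusPeak]:
    """Merge per-time-point peak sets into consensus peaks.

    All peaks are pooled; intervals on the same chromosome whose gap is
    <= ``gap`` bp are merged transitively. ``present_in`` collects the time
    points contributing at least one source peak overlapping the merged
    interval (any overlap). Output is sorted by (chrom, start) and
    independent of input order.
    """
    records: list[tuple[str, int, int, str]] = []
    for tp, peaks in peak_sets.items():
        for p in peaks:
            records.append((p.chrom, p.start, p.end, tp))
    records.sort()
    out: list[ConsensusPeak] = []
    cur: list | None = None  # [chrom, start, end, set(tp)]
    for chrom, s, e, tp in records:
        if cur is not None and chrom == cur[0] and s - cur[2] <= gap:
            cur[2] = max(cur[2], e)
            cur[3].add(tp)
        else:
            if cur is not None:
                out.append(ConsensusPeak(GenomicInterval(cur[0], cur[1], cur[2]), cur[3]))
            cur = [chrom, s, e, {tp}]
    if cur is not None:
        out.append(ConsensusPeak(GenomicInterval(cur[0], cur[1], cur[2]), cur[3]))
    return out


def venn_categories(consensus: list[ConsensusPeak]) -> pd.DataFrame:
    """Counts and integer percentages per subset of time points present."""
    total = len(consensus)
    subsets = [
        ("D0",), ("D14",), ("D28",),
        ("D0", "D14"), ("D0", "D28"), ("D14", "D28"),
        ("D0", "D14", "D28"),
    ]
    counts = {s: 0 for s in subsets}
    for pk in consensus:
        key = tuple(tp for tp in TIMEPOINTS if tp in pk.present_in)
        counts[key] += 1
    rows = [
        {
            "subset": "&".join(s),
            "count": counts[s],
            "percent": venn_percent(counts[s], total) if total else 0,
        }
        for s in subsets
    ]
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    return df


def venn_percent(count: int, total: int) -> int:
    """Share of consensus peaks in a Venn class, as an integer percent."""
    if total == 0:
        raise ValueError("empty consensus set")
    return round(100.0 * count / total)


# ---------------------------------------------------------------------------
# annotation


def promoter_interval(gene: GeneModel, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN
                      ) -> tuple[int, int]:
    """Promoter-TSS window: ``up`` bp upstream plus ``down`` bp downstream of
    the TSS, strand-oriented, as a half-open interval."""
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down, gene.tss + up


def _tts_interval(gene: GeneModel, up: int = PROMOTER_DOWN, down: int = PROMOTER_UP
                  ) -> tuple[int, int]:
    # mirror of the promoter window around the transcript end site
    if gene.strand == "+":
        return gene.tes - up, gene.tes + down
    return gene.tes - down, gene.tes + up


def annotate_peaks(
    consensus: list[ConsensusPeak],
    genes: list[GeneModel],
    up: int = PROMOTER_UP,
    down: int = PROMOTER_DOWN,
) -> list[ConsensusPeak]:
    """Assign each peak a single genomic category and its nearest gene.

    Category is decided by the peak midpoint with priority
    promoter-TSS > TTS > 5UTR > 3UTR > exon > intron > intergenic. UTR
    categories fire only for gene models carrying explicit UTR intervals.
    ``dist_to_tss`` is signed and strand-oriented (positive downstream of the
    nearest gene's TSS). Mutates and returns the peak list.
    """
    if not genes:
        logger.warning("annotate_peaks: empty annotation; all peaks intergenic")
        for pk in consensus:
            pk.category, pk.nearest_gene, pk.dist_to_tss = "intergenic", None, None
        return consensus

    prio = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}

    def add(chrom: str, s: int, e: int, cat: str, gid: str) -> None:
        if s < e:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, (cat, gid))

    for g in genes:
        ps, pe = promoter_interval(g, up, down)
        add(g.chrom, ps, pe, "promoter-TSS", g.gene_id)
        ts, te = _tts_interval(g)
        add(g.chrom, ts, te, "TTS", g.gene_id)
        for s, e in getattr(g, "utr5", []) or []:
            add(g.chrom, s, e, "5UTR", g.gene_id)
        for s, e in getattr(g, "utr3", []) or []:
            add(g.chrom, s, e, "3UTR", g.gene_id)
        for s, e in g.exons:
            add(g.chrom, s, e, "exon", g.gene_id)
        add(g.chrom, g.start, g.end, "intron", g.gene_id)  # body; beaten by exon
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g))

    tss_sorted = {
        c: sorted(v, key=lambda t: t[0]) for c, v in tss_by_chrom.items()
    }
    tss_arrays = {c: np.array([t[0] for t in v]) for c, v in tss_sorted.items()}

    for pk in consensus:
        mid = pk.interval.midpoint
        chrom = pk.interval.chrom
        hits = trees[chrom][mid] if chrom in trees else set()
        best = "intergenic"
        for h in hits:
            cat = h.data[0]
            if prio[cat] < prio[best]:
                best = cat
        pk.category = best
        # nearest gene by TSS distance
        if chrom in tss_arrays and len(tss_arrays[chrom]):
            arr = tss_arrays[chrom]
            i = int(np.searchsorted(arr, mid))
            cands = [j for j in (i - 1, i) if 0 <= j < len(arr)]
            j = min(cands, key=lambda j: abs(mid - arr[j]))
            tss, gene = tss_sorted[chrom][j][0], tss_sorted[chrom][j][1]
            pk.nearest_gene = gene.gene_id
            d = mid - tss
            pk.dist_to_tss = d if gene.strand == "+" else -d
        else:
            pk.nearest_gene, pk.dist_to_tss = None, None
    return consensus


def category_counts(consensus: list[ConsensusPeak]) -> pd.Series:
    return pd.Series([pk.category for pk in consensus]).value_counts()


# ---------------------------------------------------------------------------
# differential accessibility


def count_fragments_in_peaks(
    fragments: pd.DataFrame, peaks: list[ConsensusPeak]
) -> pd.DataFrame:
    """Per-peak, per-sample fragment counts (fragment midpoint in peak)."""
    samples = sorted(fragments["sample"].unique())
    trees: dict[str, IntervalTree] = {}
    for i, pk in enumerate(peaks):
        trees.setdefault(pk.interval.chrom, IntervalTree()).addi(
            pk.interval.start, pk.interval.end, i
        )
    mat = np.zeros((len(peaks), len(samples)), dtype=np.int64)
    sidx = {s: j for j, s in enumerate(samples)}
    mids = ((fragments["start"] + fragments["end"]) // 2).to_numpy()
    for chrom, s, mid in zip(fragments["chrom"], fragments["sample"], mids):
        if chrom in trees:
            for h in trees[chrom][int(mid)]:
                mat[h.data, sidx[s]] += 1
    idx = [pk.peak_id for pk in peaks]
    return pd.DataFrame(mat, index=idx, columns=samples)


def diff_accessibility(
    counts_in_peaks: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "AvsB",
    abs_log2fc: float = 1.5,
    p_threshold: float = 0.05,
    assumed_dispersion: float = 0.05,
) -> pd.DataFrame:
    """Differential accessibility on per-peak counts.

    Reuses the NB Wald machinery. Significance is |log2FC| > ``abs_log2fc``
    (strict) AND raw p < ``p_threshold`` — note the raw-p criterion, unlike
    the FDR-based expression rule. All-zero peaks are excluded.

    Designs without replication in either group cannot separate biological
    change from noise; they use ``assumed_dispersion`` (the edgeR-style
    plausible technical dispersion for deep libraries) and are flagged
    exploratory. Set ``assumed_dispersion=None`` to fall back to the blind
    condition-as-replicate trend, which is far more conservative when many
    regions truly change.
    """
    nonzero = counts_in_peaks[group_a + group_b].sum(axis=1) > 0
    counts = counts_in_peaks[nonzero]
    no_reps = len(group_a) < 2 and len(group_b) < 2
    res = nb_test(
        counts, group_a, group_b, comparison=comparison,
        fixed_dispersion=assumed_dispersion if no_reps else None,
    )
    res = res.rename(columns={"gene_id": "peak_id"})
    res["significant"] = (np.abs(res["log2fc"]) > abs_log2fc) & (res["p"] < p_threshold)
    res.attrs["exploratory"] = len(group_a) < 2 and len(group_b) < 2
    return res


# ---------------------------------------------------------------------------
# overlap statistics


def _build_tree(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_fraction(
    query_peaks: list[GenomicInterval], db_intervals: list[GenomicInterval]
) -> tuple[float, int, int]:
    """Fraction of query peaks with >= 1 bp intersection with the database.

    Returns (fraction, overlapping count, total)."""
    total = len(query_peaks)
    if total == 0 or not db_intervals:
        return 0.0, 0, total
    trees = _build_tree(db_intervals)
    n = sum(
        1
        for q in query_peaks
        if q.chrom in trees and trees[q.chrom].overlap(q.start, q.end)
    )
    return n / total, n, total


def overlap_percent(numerator: int, denominator: int) -> int:
    """Integer-percent report of an overlap fraction."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator)


def snp_overlap_test(
    peaks_by_class: dict[str, list[GenomicInterval]],
    snps: list[GenomicInterval],
    universe: list[GenomicInterval],
) -> pd.DataFrame:
    """Per-class hypergeometric test for SNP-containing peaks.

    M = universe peaks, K = universe peaks containing >= 1 SNP, n = peaks in
    the class, x = SNP-containing peaks in the class; exact upper-tail p with
    BH across classes. SNPs falling outside every universe interval simply
    never mark a peak.
    """
    from .profiles import hypergeom_tail
    from .expression import bh_fdr

    snp_trees = _build_tree(snps)

    def has_snp(iv: GenomicInterval) -> bool:
        return iv.chrom in snp_trees and bool(snp_trees[iv.chrom].overlap(iv.start, iv.end))

    M = len(universe)
    K = sum(1 for iv in universe if has_snp(iv))
    rows = []
    for cls in sorted(peaks_by_class):
        peaks = peaks_by_class[cls]
        n = len(peaks)
        x = sum(1 for iv in peaks if has_snp(iv))
        rows.append(
            {"class": cls, "M": M, "K": K, "n": n, "x": x,
             "p": hypergeom_tail(x, K, n, M)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def subtract_blacklist(
    peaks: list[GenomicInterval], blacklist: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop peaks overlapping any blacklisted interval (ENCODE-style filter)."""
    if not blacklist:
        return list(peaks)
    trees = _build_tree(blacklist)
    return [
        p
        for p in peaks
        if p.chrom not in trees or not trees[p.chrom].overlap(p.start, p.end)
    ]


# ---------------------------------------------------------------------------
# locus test


def locus_mw_test(
    fragments_a: pd.DataFrame,
    fragments_b: pd.DataFrame,
    locus_ocrs: list[GenomicInterval],
    total_a: int | None = None,
    total_b: int | None = None,
) -> float:
    """Two-sided Mann-Whitney U on per-OCR normalised fragment counts.

    Counts per OCR (fragment midpoint inside) are scaled per million total
    fragments of each sample. Exact p for <= 8 OCRs per side (no ties),
    normal approximation otherwise. Identical normalised count vectors (all
    ties) return p = 1 by convention. Requires >= 3 OCRs.
    """
    if len(locus_ocrs) < 3:
        raise ValueError("locus test needs >= 3 open chromatin regions")
    total_a = total_a if total_a is not None else len(fragments_a)
    total_b = total_b if total_b is not None else len(fragments_b)

    def counts(frags: pd.DataFrame) -> np.ndarray:
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        chroms = frags["chrom"].to_numpy()
        out = np.zeros(len(locus_ocrs))
        for i, ocr in enumerate(locus_ocrs):
            out[i] = np.sum((chroms == ocr.chrom) & (mids >= ocr.start) & (mids < ocr.end))
        return out

    xa = counts(fragments_a) / total_a * 1e6
    xb = counts(fragments_b) / total_b * 1e6
    if np.array_equal(np.sort(xa), np.sort(xb)) and len(np.unique(np.concatenate([xa, xb]))) == 1:
        return 1.0
    n = len(locus_ocrs)
    method = "exact" if n <= 8 and len(np.unique(np.concatenate([xa, xb]))) == 2 * n else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return float(res.pvalue)
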