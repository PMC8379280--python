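"""Normalisation, FPKM and negative-binomial differential expression.

The differential test follows the DESeq2 recipe in spirit — median-of-ratios
size factors, per-gene method-of-moments NB dispersion shrunk toward a
parametric mean-dispersion trend, and a Wald test on log2 fold-change of
normalised counts — without the IRLS GLM machinery. Downstream analyses
consume ranked log2FC and BH-adjusted q-values, for which this moderated
Wald test is calibrated (see the type-I-error tests).

A gene is called differentially expressed (DEG) under the three-way rule:
BH FDR < 0.05, linear fold-change of normalised means > 4 (i.e. |log2FC| > 2)
and FPKM >= 1 in at least one replicate of the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

logger = logging.getLogger(__name__)

COMPARISONS = ("D0vsD14", "D14vsD28", "D0vsD28")

#: thresholds of the DEG rule
DEG_FC = 4.0
DEG_FDR = 0.05
FPKM_MIN = 1.0


@dataclass
class DEResult:
    gene_id: str
    comparison: str
    base_mean: float
    log2fc: float
    p: float
    q: float = np.nan
    is_deg: bool = False


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios normalisation factors, one per sample.

    The reference is the per-gene geometric mean across samples; genes with a
    zero count in any sample are excluded from the median.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "consider a pseudo-reference fallback"
        )
    sub = arr[all_nonzero]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts / factors


def fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm_ij = count_ij / (length_i/1e3 * total_j/1e6)``. ``totals`` defaults
    to the per-sample column sums.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero total mapped reads for some sample")
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def _dispersion_trend(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by least squares on genes with usable
    moment estimates; returns (a0, a1), both floored at small positives."""
    ok = (means > 1e-8) & (disps > 1e-7)
    if ok.sum() < 10:
        med = float(np.median(disps[disps > 0])) if (disps > 0).any() else 0.1
        return max(med, 1e-6), 1e-6
    x = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(x, disps[ok], rcond=None)
    return max(float(coef[0]), 1e-6), max(float(coef[1]), 1e-6)


def nb_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
    comparison: str = "AvsB",
    shrink_weight: float = 0.6,
    fixed_dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A on normalised counts.

    Dispersion is the pooled within-group method-of-moments estimate
    (floored at 1e-8), shrunk toward the fitted mean-dispersion trend in log
    space with weight ``shrink_weight``. The Wald statistic is
    log2FC / SE(log2FC) with a 0.5 pseudo-count on the group means and a
    two-sided normal p. All-zero genes get log2fc = 0, p = 1.

    Returns a DataFrame with gene_id, comparison, base_mean, log2fc, p, q.
    """
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValueError("each group needs at least one sample")
    if factors is None:
        factors = size_factors(counts[group_a + group_b])
    norm = normalize_counts(counts[group_a + group_b], factors.loc[group_a + group_b])
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)

    # pooled within-group MoM dispersion: alpha = (var - mu) / mu^2
    dof = max(na - 1, 0) + max(nb - 1, 0)
    mu = np.where(base_mean > 0, base_mean, 1.0)
    if fixed_dispersion is not None:
        disp_gene = np.full(len(norm), float(fixed_dispersion))
        dof, w = 0, 1.0
    elif dof > 0:
        ss = np.zeros(len(norm))
        if na > 1:
            ss += ((a - mean_a[:, None]) ** 2).sum(axis=1)
        if nb > 1:
            ss += ((b - mean_b[:, None]) ** 2).sum(axis=1)
        pooled_var = ss / dof
        disp_gene = np.maximum((pooled_var - mu) / mu**2, 1e-8)
        w = shrink_weight
    else:
        # no replication in either group: blind estimate across all samples,
        # treating condition as replicate (conservative); trend used fully
        logger.warning(
            "nb_test %s: no replicated group; dispersion taken from the "
            "blind mean-variance trend — results are exploratory", comparison
        )
        both = norm.to_numpy(dtype=float)
        blind_var = both.var(axis=1, ddof=1)
        disp_gene = np.maximum((blind_var - mu) / mu**2, 1e-8)
        w = 1.0

    if fixed_dispersion is not None:
        disp = disp_gene
    else:
        a0, a1 = _dispersion_trend(base_mean, disp_gene)
        disp_trend = np.maximum(a0 + a1 / mu, 1e-8)
        disp = np.exp((1 - w) * np.log(disp_gene) + w * np.log(disp_trend))

    pa, pb = mean_a + 0.5, mean_b + 0.5
    log2fc = np.log2(pb) - np.log2(pa)
    # delta method on log of the group mean of NB samples
    var_log_a = (mean_a + disp * mean_a**2) / (na * pa**2)
    var_log_b = (mean_b + disp * mean_b**2) / (nb * pb**2)
    se = np.sqrt(var_log_a + var_log_b) / np.log(2)
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    # t reference guards small-sample tail calibration; shrinkage toward the
    # trend stabilises the variance estimate, so the effective df exceeds the
    # residual df by 1/(1 - shrink weight)
    df_eff = dof / max(1.0 - w, 1e-9) if dof > 0 else np.inf
    if df_eff < 30:
        p = 2.0 * stats.t.sf(np.abs(z), df=df_eff)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))

    allzero = (mean_a == 0) & (mean_b == 0)
    log2fc[allzero] = 0.0
    p[allzero] = 1.0

    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "comparison": comparison,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": np.clip(p, 0.0, 1.0),
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` with stable ties. NaN p-values
    propagate as NaN (with a warning) and are excluded from m.
    """
    p = np.asarray(pvals, dtype=float)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        logger.warning("bh_fdr: %d NaN p-values propagated", int(nan_mask.sum()))
    q = np.full_like(p, np.nan)
    pv = p[~nan_mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    q[~nan_mask] = res
    return q


def run_comparisons(
    cm: CountMatrix,
    timepoints: tuple[str, str, str] = ("D0", "D14", "D28"),
) -> dict[str, pd.DataFrame]:
    """Run the three pairwise NB tests of the time course with shared size
    factors, returning a comparison-label -> results table mapping."""
    factors = size_factors(cm.counts)
    pairs = {
        f"{timepoints[0]}vs{timepoints[1]}": (timepoints[0], timepoints[1]),
        f"{timepoints[1]}vs{timepoints[2]}": (timepoints[1], timepoints[2]),
        f"{timepoints[0]}vs{timepoints[2]}": (timepoints[0], timepoints[2]),
    }
    out = {}
    for label, (ta, tb) in pairs.items():
        out[label] = nb_test(
            cm.counts, cm.samples_at(ta), cm.samples_at(tb), factors, comparison=label
        )
    return out


def call_degs(
    de_tables: dict[str, pd.DataFrame],
    fpkm_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    biotypes: pd.Series | None = None,
    fc_threshold: float = DEG_FC,
    fdr_threshold: float = DEG_FDR,
    fpkm_min: float = FPKM_MIN,
) -> pd.DataFrame:
    """Apply the three-way DEG rule per comparison and compile the union.

    A gene is a DEG in a comparison when q < ``fdr_threshold``, linear
    |FC| > ``fc_threshold`` and at least one replicate of the two compared
    time points has FPKM >= ``fpkm_min``. Returns the concatenated
    per-comparison tables with an ``is_deg`` column (and ``biotype`` when
    supplied); the compiled DEG list is the union over comparisons.
    """
    frames = []
    log2_thr = np.log2(fc_threshold)
    for label, table in de_tables.items():
        ta, _, tb = label.partition("vs")
        samples = list(meta.index[meta["timepoint"].isin([ta, tb])])
        tab = table.copy()
        known = tab["gene_id"].isin(fpkm_matrix.index)
        if (~known).any():
            logger.warning(
                "%s: %d genes missing FPKM excluded", label, int((~known).sum())
            )
            tab = tab[known]
        max_fpkm = fpkm_matrix.loc[tab["gene_id"], samples].max(axis=1).to_numpy()
        tab["max_fpkm"] = max_fpkm
        tab["is_deg"] = (
            (tab["q"] < fdr_threshold)
            & (np.abs(tab["log2fc"]) > log2_thr)
            & (max_fpkm >= fpkm_min)
        )
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    if biotypes is not None:
        out["biotype"] = biotypes.reindex(out["gene_id"]).to_numpy()
    return out


def compiled_deg_list(deg_table: pd.DataFrame) -> list[str]:
    """Union of DEGs across the three comparisons, sorted for determinism."""
    return sorted(deg_table.loc[deg_table["is_deg"], "gene_id"].unique())
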