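"""Synthetic-data generator for the whole pipeline.

Emulates the statistical structure of a three-time-point (D0/D14/D28)
dopaminergic-differentiation study: negative-binomial RNA counts over six
temporal expression archetypes spanning protein-coding and lncRNA biotypes
(3/4/3 replicates), an ATAC fragment-size mixture with sub-100 bp
open-chromatin mass plus nucleosome modes at 200/440/600 bp, time-point
specific and shared peaks, a tunable positive coupling between promoter
accessibility change and expression change, promoter sequences with planted
motif occurrences, and enhancer/SNP tables with controllable enrichment.

Every generator draws all randomness from ``SimConfig.seed`` (one
sub-stream per stage) and emits a truth table sufficient to score
downstream recovery. Identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneModel, GenomicInterval, LNCRNA_BIOTYPES, PWM

TIMEPOINTS = ("D0", "D14", "D28")

DEFAULT_BIOTYPE_FRACTIONS = {
    "protein_coding": 0.70,
    "lincRNA": 0.12,
    "antisense": 0.08,
    "sense_intronic": 0.03,
    "processed_transcript": 0.04,
    "sense_overlapping": 0.02,
    "TEC": 0.01,
}

#: temporal archetypes as log2 shifts per time point (D0, D14, D28), scaled
#: per gene: 1 down at D14 staying down; 2 down at D14, back up at D28;
#: 3 high until D14, down at D28; 4 up at D14 settling above baseline;
#: 5 transient D14 peak; 6 up at D28.
ARCHETYPE_PATTERNS = {
    1: (0.0, -1.0, -1.0),
    2: (0.0, -1.0, 0.0),
    3: (0.0, 0.0, -1.0),
    4: (0.0, 1.0, 0.5),
    5: (0.0, 1.0, 0.0),
    6: (0.0, 0.0, 1.0),
}

#: Venn-class proportions for background peaks, mirroring the study's shape
DEFAULT_PEAK_CLASS_PROPS = {
    ("D0",): 0.22,
    ("D14",): 0.32,
    ("D28",): 0.19,
    ("D0", "D14"): 0.06,
    ("D0", "D28"): 0.04,
    ("D14", "D28"): 0.06,
    ("D0", "D14", "D28"): 0.11,
}


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 2000
    biotype_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_FRACTIONS)
    )
    replicates: tuple[int, int, int] = (3, 4, 3)
    n_clusters: int = 6
    null_fraction: float = 0.3  # flat genes, for type-I-error testing
    nb_dispersion: float = 0.1
    base_mean: float = 100.0  # median RNA normalised count of a gene
    archetype_log2fc: float = 3.0  # mean magnitude of the archetype shift (FC 8)
    archetype_log2fc_sd: float = 0.8
    batch_effects: dict | None = None  # batch label -> multiplier
    # ATAC
    n_peaks: int = 10000
    peak_class_props: dict = field(
        default_factory=lambda: dict(DEFAULT_PEAK_CLASS_PROPS)
    )
    peak_width: tuple[int, int] = (200, 500)
    atac_base_mean: float = 500.0
    atac_dispersion: float = 0.05
    open_log2fc: float = 3.0  # closed-vs-open accessibility shift of class peaks
    d0_global_boost: float = 1.2  # global accessibility excess at D0
    coupling_rho: float = 0.45
    coupled_acc_sd: float = 2.0  # sd of promoter accessibility log2FC
    # fragment-size mixture: sub-100 bp open chromatin + nucleosome modes
    fragment_weights: tuple[float, float, float, float] = (0.50, 0.28, 0.14, 0.08)
    nucleosome_modes: tuple[float, float, float] = (200.0, 440.0, 600.0)
    nucleosome_sigmas: tuple[float, float, float] = (25.0, 40.0, 50.0)
    sub100_offset: float = 40.0
    sub100_scale: float = 20.0
    fragment_background_rate: float = 0.05
    # motifs
    motif_plant_rate: dict = field(default_factory=dict)  # (cluster, motif_id) -> rate
    # enhancers / SNPs
    enhancer_fraction: float = 0.6  # of D0-specific peaks covered by the DB
    n_snps: int = 2000
    snp_odds: float = 1.0  # enrichment odds in D28-specific intron/intergenic peaks

    def __post_init__(self) -> None:
        if abs(sum(self.biotype_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("biotype fractions must sum to 1")
        if abs(sum(self.peak_class_props.values()) - 1.0) > 1e-9:
            raise ValueError("peak class proportions must sum to 1")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must be in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stage])


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    cfg: SimConfig,
) -> tuple[list[GeneModel], dict[str, str], dict[str, int]]:
    """Genes tiled on synthetic chromosomes with >= 10 kb spacing.

    Antisense and sense_intronic lncRNAs get the adjacent protein-coding
    gene as their annotated regulatory target. Returns (genes, promoter
    sequences of 2001 bp centered on each TSS, chromosome sizes).
    """
    if cfg.n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    rng = cfg.rng(1)
    biotypes = list(cfg.biotype_fractions)
    probs = np.array([cfg.biotype_fractions[b] for b in biotypes])
    assigned = rng.choice(len(biotypes), size=cfg.n_genes, p=probs)

    genes: list[GeneModel] = []
    genes_per_chrom = 200
    pos = 20000
    chrom_idx = 1
    chrom_sizes: dict[str, int] = {}
    last_coding: str | None = None
    pending_targets: list[int] = []  # gene indices awaiting a downstream coding target
    for i in range(cfg.n_genes):
        chrom = f"chr{chrom_idx}"
        length = int(rng.integers(2000, 20001))
        n_exons = int(rng.integers(1, 5))
        cuts = np.sort(rng.integers(0, length, size=2 * n_exons))
        exons = [
            (pos + int(cuts[2 * j]), pos + int(cuts[2 * j + 1]))
            for j in range(n_exons)
            if cuts[2 * j] < cuts[2 * j + 1]
        ] or [(pos, pos + length)]
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[assigned[i]]
        gid = f"G{i:05d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                name=f"GENE{i}",
                chrom=chrom,
                strand=strand,
                start=pos,
                end=pos + length,
                biotype=biotype,
                exons=exons,
            )
        )
        if biotype == "protein_coding":
            for j in pending_targets:
                genes[j].target_gene_id = gid
            pending_targets = []
            last_coding = gid
        elif biotype in ("antisense", "sense_intronic"):
            if last_coding is not None:
                genes[-1].target_gene_id = last_coding
            else:
                pending_targets.append(len(genes) - 1)
        pos += length + 10000 + int(rng.integers(0, 5000))
        if (i + 1) % genes_per_chrom == 0:
            chrom_sizes[chrom] = pos + 20000
            chrom_idx += 1
            pos = 20000
    chrom_sizes[f"chr{chrom_idx}"] = pos + 20000

    bases = np.array(list("ACGT"))
    promoters = {
        g.gene_id: "".join(bases[rng.integers(0, 4, size=2001)]) for g in genes
    }
    return genes, promoters, chrom_sizes


# ---------------------------------------------------------------------------
# RNA counts


def gen_counts(
    cfg: SimConfig, genes: list[GeneModel]
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts over the six temporal archetypes.

    A ``null_fraction`` of genes is flat across time (cluster 0 in the truth
    table). Each non-null gene gets an archetype and a gene-specific log2
    magnitude ~ Normal(archetype_log2fc, archetype_log2fc_sd) truncated at 1.
    Counts ~ NB(mean = library factor x archetype mean, dispersion
    ``nb_dispersion``); dispersion 0 is the Poisson limit. Returns the count
    matrix (with metadata) and the truth table with planted per-comparison
    log2 fold-changes.
    """
    rng = cfg.rng(2)
    n = len(genes)
    clusters = np.zeros(n, dtype=int)
    non_null = rng.random(n) >= cfg.null_fraction
    clusters[non_null] = rng.integers(1, cfg.n_clusters + 1, size=int(non_null.sum()))
    base = rng.lognormal(np.log(cfg.base_mean), 1.0, size=n)
    mags = np.maximum(
        rng.normal(cfg.archetype_log2fc, cfg.archetype_log2fc_sd, size=n), 1.0
    )
    mags[~non_null] = 0.0

    shifts = np.zeros((n, 3))
    for c, pattern in ARCHETYPE_PATTERNS.items():
        mask = clusters == c
        shifts[mask] = np.array(pattern)[None, :] * mags[mask, None]
    means = base[:, None] * 2.0 ** shifts  # genes x time points

    samples, tps, reps, batches = [], [], [], []
    for tp, nrep in zip(TIMEPOINTS, cfg.replicates):
        for r in range(1, nrep + 1):
            samples.append(f"{tp}_r{r}")
            tps.append(tp)
            reps.append(r)
            batches.append(f"batch{r % 2 + 1}")
    lib = rng.lognormal(0.0, 0.1, size=len(samples))
    if cfg.batch_effects:
        lib = lib * np.array([cfg.batch_effects.get(b, 1.0) for b in batches])

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    for j, (s, tp) in enumerate(zip(samples, tps)):
        mu = means[:, tp_index[tp]] * lib[j]
        if cfg.nb_dispersion > 0:
            r_nb = 1.0 / cfg.nb_dispersion
            counts[:, j] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    cm = CountMatrix(
        pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=samples),
        pd.DataFrame(
            {"timepoint": tps, "replicate": reps, "batch": batches}, index=samples
        ),
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "biotype": [g.biotype for g in genes],
            "cluster": clusters,
            "base_mean": base,
            "lfc_D0vsD14": shifts[:, 1] - shifts[:, 0],
            "lfc_D14vsD28": shifts[:, 2] - shifts[:, 1],
            "lfc_D0vsD28": shifts[:, 2] - shifts[:, 0],
        }
    ).set_index("gene_id")
    return cm, truth


# ---------------------------------------------------------------------------
# peaks


@dataclass
class PeakSim:
    peak_sets: dict[str, list[GenomicInterval]]  # MACS-like per-time-point calls
    counts: pd.DataFrame  # peaks x 3 ATAC samples
    truth: pd.DataFrame  # per-peak class, kind, coupled gene, planted acc lfc
    intervals: list[GenomicInterval]  # all distinct peaks (truth order)


def gen_peaks(
    cfg: SimConfig,
    genes: list[GeneModel],
    expr_truth: pd.DataFrame,
    chrom_sizes: dict[str, int],
) -> PeakSim:
    """Per-time-point peak sets with planted Venn structure and coupling.

    Background peaks fall into time-point-specific / shared classes with the
    configured proportions. Every protein-coding gene gets a promoter peak,
    present at all time points, whose D0->D28 accessibility log2FC correlates
    with the gene's planted expression log2FC at ``coupling_rho`` (shared
    latent + independent noise). D0 counts carry a global accessibility
    boost.
    """
    rng = cfg.rng(3)
    peaks: list[GenomicInterval] = []
    classes: list[tuple[str, ...]] = []
    kinds: list[str] = []
    coupled_gene: list[str | None] = []

    coding = [g for g in genes if g.biotype == "protein_coding"]
    for g in coding:
        width = int(rng.integers(*cfg.peak_width))
        mid = g.tss
        peaks.append(GenomicInterval(g.chrom, mid - width // 2, mid + width - width // 2,
                                     name=f"prom_{g.gene_id}"))
        classes.append(TIMEPOINTS)
        kinds.append("promoter")
        coupled_gene.append(g.gene_id)

    n_bg = max(cfg.n_peaks - len(coding), 0)
    class_keys = sorted(cfg.peak_class_props)
    class_p = np.array([cfg.peak_class_props[k] for k in class_keys])
    chosen = rng.choice(len(class_keys), size=n_bg, p=class_p)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        occupied.setdefault(p.chrom, []).append((p.start, p.end))
    # background peaks stay intergenic: accessibility of gene-proximal
    # regions tracks expression, which is the promoter peaks' job here
    blocked: dict[str, np.ndarray] = {}
    for g in genes:
        blocked.setdefault(g.chrom, [])
        blocked[g.chrom].append((g.start - 2000, g.end + 2000))
    blocked = {
        c: np.array(sorted(v), dtype=float).reshape(-1, 2) for c, v in blocked.items()
    }
    for i in range(n_bg):
        width = int(rng.integers(*cfg.peak_width))
        for _ in range(200):  # rejection-sample an intergenic, isolated spot
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            chrom = chroms[ci]
            start = int(rng.integers(1000, chrom_sizes[chrom] - width - 1000))
            if chrom in blocked and len(blocked[chrom]):
                arr = blocked[chrom]
                j = int(np.searchsorted(arr[:, 0], start + width))
                genic = j > 0 and arr[j - 1, 1] > start
                if genic:
                    continue
            ok = all(
                start > e + 200 or start + width < s - 200
                for s, e in occupied.get(chrom, [])
            )
            if ok:
                break
        occupied.setdefault(chrom, []).append((start, start + width))
        peaks.append(GenomicInterval(chrom, start, start + width, name=f"bg_{i}"))
        classes.append(tuple(class_keys[chosen[i]]))
        kinds.append("background")
        coupled_gene.append(None)

    # planted accessibility log2FC (D0 -> D28) for promoter peaks
    n_peaks = len(peaks)
    acc_lfc = np.zeros(n_peaks)
    expr_lfc = expr_truth["lfc_D0vsD28"]
    x = expr_lfc.loc[[g.gene_id for g in coding]].to_numpy()
    sx = x.std() if x.std() > 1e-12 else 1.0
    rho = cfg.coupling_rho
    noise = rng.normal(0.0, 1.0, size=len(coding))
    acc_lfc[: len(coding)] = cfg.coupled_acc_sd * (
        rho * (x - x.mean()) / sx + np.sqrt(max(1.0 - rho**2, 0.0)) * noise
    )

    # per-peak, per-time-point NB counts
    mu = np.zeros((n_peaks, 3))
    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    for i in range(n_peaks):
        if kinds[i] == "promoter":
            d28 = cfg.atac_base_mean * 2.0 ** acc_lfc[i]
            d14 = np.sqrt(cfg.atac_base_mean * d28)
            mu[i] = (cfg.atac_base_mean, d14, d28)
        else:
            closed = cfg.atac_base_mean / 2.0**cfg.open_log2fc
            for tp in TIMEPOINTS:
                mu[i, tp_index[tp]] = (
                    cfg.atac_base_mean if tp in classes[i] else closed
                )
    mu[:, 0] *= cfg.d0_global_boost
    r_nb = 1.0 / cfg.atac_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu)).astype(np.int64)

    peak_sets: dict[str, list[GenomicInterval]] = {tp: [] for tp in TIMEPOINTS}
    for i, p in enumerate(peaks):
        for tp in classes[i]:
            peak_sets[tp].append(GenomicInterval(p.chrom, p.start, p.end, name=p.name))
    peak_ids = [f"{p.chrom}:{p.start}-{p.end}" for p in peaks]
    truth = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "kind": kinds,
            "class": ["&".join(c) for c in classes],
            "coupled_gene": coupled_gene,
            "acc_lfc_D0vsD28": acc_lfc,
        }
    ).set_index("peak_id")
    count_df = pd.DataFrame(
        counts, index=peak_ids, columns=[f"{tp}_atac" for tp in TIMEPOINTS]
    )
    return PeakSim(peak_sets=peak_sets, counts=count_df, truth=truth, intervals=peaks)


# ---------------------------------------------------------------------------
# fragments


def sample_fragment_sizes(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sizes from the four-component mixture: truncated shifted exponential
    below 100 bp plus Gaussians at the nucleosome modes."""
    w = np.asarray(cfg.fragment_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(4, size=n, p=w)
    sizes = np.empty(n)
    sub = comp == 0
    n_sub = int(sub.sum())
    draws = cfg.sub100_offset + rng.exponential(cfg.sub100_scale, size=n_sub)
    while (draws >= 100).any():  # truncate at 100 bp by resampling
        bad = draws >= 100
        draws[bad] = cfg.sub100_offset + rng.exponential(cfg.sub100_scale, size=int(bad.sum()))
    sizes[sub] = draws
    for k in range(3):
        mask = comp == k + 1
        sizes[mask] = rng.normal(
            cfg.nucleosome_modes[k], cfg.nucleosome_sigmas[k], size=int(mask.sum())
        )
    return np.maximum(sizes, 10.0)


def gen_fragments(
    cfg: SimConfig,
    peak_sets: dict[str, list[GenomicInterval]],
    chrom_sizes: dict[str, int],
    n_fragments: int = 200000,
    samples: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Fragment table (chrom, start, end, sample, strand).

    Fragment midpoints land inside a random open peak of the sample's time
    point, except a ``fragment_background_rate`` fraction placed uniformly on
    the genome. Sizes come from the nucleosome mixture.
    """
    rng = cfg.rng(4)
    samples = samples or TIMEPOINTS
    per_sample = n_fragments // len(samples)
    chroms = sorted(chrom_sizes)
    sizes_arr = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    rows = []
    for sample in samples:
        tp = sample.split("_")[0]
        open_peaks = peak_sets.get(tp, [])
        frag_sizes = sample_fragment_sizes(cfg, per_sample, rng).astype(int)
        in_bg = rng.random(per_sample) < cfg.fragment_background_rate
        if not open_peaks:
            in_bg[:] = True
        peak_idx = rng.integers(0, max(len(open_peaks), 1), size=per_sample)
        bg_chrom = rng.choice(len(chroms), size=per_sample, p=sizes_arr / sizes_arr.sum())
        bg_pos = (rng.random(per_sample) * (sizes_arr[bg_chrom] - 2000) + 1000).astype(int)
        u = rng.random(per_sample)
        strands = np.where(rng.random(per_sample) < 0.5, "+", "-")
        for i in range(per_sample):
            size = int(frag_sizes[i])
            if in_bg[i]:
                chrom = chroms[bg_chrom[i]]
                mid = int(bg_pos[i])
            else:
                pk = open_peaks[int(peak_idx[i])]
                chrom = pk.chrom
                mid = pk.start + int(u[i] * len(pk))
            start = max(mid - size // 2, 0)
            rows.append((chrom, start, start + size, sample, strands[i]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "strand"])


# ---------------------------------------------------------------------------
# motif planting


def default_pwms(n: int = 4, length: int = 12, info: float = 0.9, seed: int = 12345
                 ) -> list[PWM]:
    """Information-rich PWMs of realistic TF-motif length.

    Each position puts probability ``info`` on a random consensus base; at
    12 bp this gives minimum p-values ~1e-7, deep enough to survive BH over
    megabase-scale promoter scans (short weak motifs cannot, which is why
    the default emulates the length of curated TF matrices).
    """
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        cons = rng.integers(0, 4, size=length)
        probs = np.full((length, 4), (1.0 - info) / 3.0)
        probs[np.arange(length), cons] = info
        pwms.append(PWM(f"M{i + 1}", f"TF{i + 1}", probs / probs.sum(axis=1, keepdims=True)))
    return pwms


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    bases = "ACGT"
    return "".join(
        bases[rng.choice(4, p=row / row.sum())] for row in pwm.probs
    )


def gen_motif_plant(
    cfg: SimConfig,
    pwms: list[PWM],
    promoters: dict[str, str],
    clusters: pd.Series,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert PWM-sampled sites into promoters at per-(cluster, motif) rates.

    ``cfg.motif_plant_rate`` maps (cluster, motif_id) -> probability that a
    promoter of that cluster receives one site of that motif. Returns the
    modified promoter set and a truth table (gene, motif, position, strand).
    """
    rng = cfg.rng(5)
    out = dict(promoters)
    rows = []
    for gene in sorted(out):
        cluster = int(clusters.get(gene, 0))
        for pwm in pwms:
            rate = cfg.motif_plant_rate.get((cluster, pwm.motif_id), 0.0)
            if rate <= 0 or rng.random() >= rate:
                continue
            site = sample_site(pwm, rng)
            if rng.random() < 0.5:
                from .motifs import reverse_complement

                site_seq, strand = reverse_complement(site), "-"
            else:
                site_seq, strand = site, "+"
            seq = out[gene]
            pos = int(rng.integers(0, len(seq) - len(site_seq) + 1))
            out[gene] = seq[:pos] + site_seq + seq[pos + len(site_seq):]
            rows.append(
                {"gene_id": gene, "motif_id": pwm.motif_id, "position": pos,
                 "strand": strand, "site": site_seq}
            )
    truth = pd.DataFrame(
        rows, columns=["gene_id", "motif_id", "position", "strand", "site"]
    )
    return out, truth


# ---------------------------------------------------------------------------
# enhancer DB and SNPs


def gen_enhancer_db_and_snps(
    cfg: SimConfig,
    peak_truth: pd.DataFrame,
    chrom_sizes: dict[str, int],
    target_class: str = "D28",
    target_categories: tuple[str, ...] = ("intron", "intergenic"),
    peak_categories: pd.Series | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Enhancer database and SNP positions with controllable enrichment.

    The enhancer DB covers ``enhancer_fraction`` of D0-specific peaks (plus
    decoy intervals). SNPs fall inside ``target_class``-specific peaks of the
    target annotation categories with odds ``snp_odds`` relative to a uniform
    genomic background; odds 1 means fully uniform placement.
    """
    rng = cfg.rng(6)
    d0 = peak_truth[peak_truth["class"] == "D0"]
    n_cover = int(round(cfg.enhancer_fraction * len(d0)))
    covered = rng.choice(len(d0), size=n_cover, replace=False) if n_cover else []
    enhancers = [
        GenomicInterval(
            d0.iloc[i]["chrom"],
            int(d0.iloc[i]["start"]) - int(rng.integers(0, 200)),
            int(d0.iloc[i]["end"]) + int(rng.integers(0, 200)),
            name=f"enh_{i}",
        )
        for i in sorted(covered)
    ]
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    for j in range(len(enhancers) // 2):  # decoys off-peak
        ci = rng.choice(len(chroms), p=sizes / sizes.sum())
        start = int(rng.integers(1000, chrom_sizes[chroms[ci]] - 2000))
        enhancers.append(
            GenomicInterval(chroms[ci], start, start + int(rng.integers(200, 800)),
                            name=f"enh_decoy_{j}")
        )

    target = peak_truth[peak_truth["class"] == target_class]
    if peak_categories is not None:
        cats = peak_categories.reindex(target.index)
        target = target[cats.isin(target_categories).to_numpy()]
    t_bp = float((target["end"] - target["start"]).sum())
    g_bp = float(sizes.sum())
    odds = cfg.snp_odds
    p_target = odds * t_bp / (odds * t_bp + (g_bp - t_bp)) if t_bp else 0.0
    snps = []
    in_target = rng.random(cfg.n_snps) < p_target
    t_starts = target["start"].to_numpy() if len(target) else np.array([0])
    t_widths = (target["end"] - target["start"]).to_numpy() if len(target) else np.array([1])
    t_chroms = target["chrom"].to_numpy() if len(target) else np.array(["chr1"])
    t_w = t_widths / t_widths.sum() if len(target) else np.array([1.0])
    t_by_chrom: dict[str, np.ndarray] = {}
    for c in set(t_chroms):
        mask = t_chroms == c
        t_by_chrom[str(c)] = np.sort(
            np.column_stack([t_starts[mask], t_starts[mask] + t_widths[mask]]), axis=0
        )

    def inside_target(chrom: str, pos: int) -> bool:
        arr = t_by_chrom.get(chrom)
        if arr is None or not len(arr):
            return False
        j = int(np.searchsorted(arr[:, 0], pos, side="right"))
        return j > 0 and arr[j - 1, 1] > pos

    for i in range(cfg.n_snps):
        if in_target[i] and len(target):
            j = rng.choice(len(t_starts), p=t_w)
            pos = int(t_starts[j] + rng.integers(0, t_widths[j]))
            chrom = t_chroms[j]
        else:
            # uniform on the complement of the target region
            for _ in range(100):
                ci = rng.choice(len(chroms), p=sizes / sizes.sum())
                chrom = chroms[ci]
                pos = int(rng.integers(0, chrom_sizes[chrom] - 1))
                if not inside_target(chrom, pos):
                    break
        snps.append(GenomicInterval(chrom, pos, pos + 1, name=f"rs{i}"))
    return enhancers, snps
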