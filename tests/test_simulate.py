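import numpy as np
import pandas as pd
import pytest

from atacrna import simulate as sim
from atacrna.io import LNCRNA_BIOTYPES


def small_cfg(**kw):
    base = dict(seed=7, n_genes=400, n_peaks=1500)
    base.update(kw)
    return sim.SimConfig(**base)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        fr = dict(sim.DEFAULT_BIOTYPE_FRACTIONS)
        fr["protein_coding"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            sim.SimConfig(biotype_fractions=fr)

    def test_peak_props_must_sum_to_one(self):
        props = dict(sim.DEFAULT_PEAK_CLASS_PROPS)
        props[("D0",)] += 0.2
        with pytest.raises(ValueError, match="sum to 1"):
            sim.SimConfig(peak_class_props=props)

    def test_rho_bounds(self):
        with pytest.raises(ValueError):
            sim.SimConfig(coupling_rho=1.5)


class TestAnnotation:
    def test_determinism_byte_identical(self, tmp_path):
        from atacrna import io

        for run in ("a", "b"):
            cfg = small_cfg()
            genes, promoters, _ = sim.gen_annotation(cfg)
            io.write_gene_models(genes, tmp_path / f"{run}.gtf")
            io.write_fasta(promoters, tmp_path / f"{run}.fa")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_spacing_and_promoter_length(self):
        genes, promoters, _ = sim.gen_annotation(small_cfg())
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist = sorted(glist, key=lambda g: g.start)
            gaps = [b.start - a.end for a, b in zip(glist, glist[1:])]
            assert all(g >= 10_000 for g in gaps)
        assert all(len(s) == 2001 for s in promoters.values())

    def test_antisense_genes_have_targets(self):
        cfg = sim.SimConfig(seed=1, n_genes=1000)
        genes, _, _ = sim.gen_annotation(cfg)
        antisense = [g for g in genes if g.biotype == "antisense"]
        assert 25 <= len(antisense) <= 120  # ~5% of 1000, generously banded
        coding_ids = {g.gene_id for g in genes if g.biotype == "protein_coding"}
        with_target = [g for g in antisense if g.target_gene_id in coding_ids]
        assert len(with_target) / len(antisense) > 0.95

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            sim.gen_annotation(sim.SimConfig(n_genes=50))


class TestCounts:
    def test_replicate_design(self):
        genes, _, _ = sim.gen_annotation(small_cfg())
        cm, _ = sim.gen_counts(small_cfg(), genes)
        reps = cm.meta["timepoint"].value_counts()
        assert (reps["D0"], reps["D14"], reps["D28"]) == (3, 4, 3)

    def test_null_genes_have_centered_fc(self):
        cfg = small_cfg(null_fraction=1.0)
        genes, _, _ = sim.gen_annotation(cfg)
        cm, truth = sim.gen_counts(cfg, genes)
        d0 = cm.counts[cm.samples_at("D0")].mean(axis=1) + 0.5
        d28 = cm.counts[cm.samples_at("D28")].mean(axis=1) + 0.5
        lfc = np.log2(d28 / d0)
        assert abs(np.median(lfc)) < 0.15

    def test_cluster6_up_at_d28(self):
        cfg = small_cfg(null_fraction=0.0)
        genes, _, _ = sim.gen_annotation(cfg)
        cm, truth = sim.gen_counts(cfg, genes)
        c6 = truth.index[truth["cluster"] == 6]
        d0 = cm.counts.loc[c6, cm.samples_at("D0")].mean(axis=1)
        d28 = cm.counts.loc[c6, cm.samples_at("D28")].mean(axis=1)
        assert (d28 > d0).mean() >= 0.95

    def test_zero_dispersion_is_poisson_limit(self):
        from atacrna.expression import normalize_counts, size_factors

        cfg = small_cfg(nb_dispersion=0.0, null_fraction=1.0)
        genes, _, _ = sim.gen_annotation(cfg)
        cm, _ = sim.gen_counts(cfg, genes)
        norm = normalize_counts(cm.counts, size_factors(cm.counts))
        d14 = norm[cm.samples_at("D14")]
        m = d14.mean(axis=1)
        v = d14.var(axis=1, ddof=1)
        big = m > 50
        # Poisson: variance ~ mean; regression slope near 1 on log scale
        slope = np.polyfit(np.log(m[big]), np.log(v[big] + 0.5), 1)[0]
        assert 0.8 < slope < 1.2

    def test_truth_lfc_consistent_with_patterns(self):
        cfg = small_cfg(null_fraction=0.0)
        genes, _, _ = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        c1 = truth[truth["cluster"] == 1]
        assert (c1["lfc_D0vsD14"] < 0).all() and (c1["lfc_D14vsD28"] == 0).all()


class TestPeaks:
    def test_class_proportions_recovered_from_labels(self):
        cfg = sim.SimConfig(seed=3)
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        ps = sim.gen_peaks(cfg, genes, truth, chrom_sizes)
        bg = ps.truth[ps.truth["kind"] == "background"]
        props = bg["class"].value_counts(normalize=True)
        for key, expected in cfg.peak_class_props.items():
            assert props["&".join(key)] == pytest.approx(expected, abs=0.03)

    def test_coupling_rho_realised(self):
        cfg = sim.SimConfig(seed=5, coupling_rho=0.5)
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        ps = sim.gen_peaks(cfg, genes, truth, chrom_sizes)
        prom = ps.truth[ps.truth["kind"] == "promoter"]
        x = truth.loc[prom["coupled_gene"], "lfc_D0vsD28"].to_numpy()
        y = prom["acc_lfc_D0vsD28"].to_numpy()
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5, abs=0.07)

    def test_zero_coupling_independent(self):
        cfg = sim.SimConfig(seed=6, coupling_rho=0.0, n_genes=3000)
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        ps = sim.gen_peaks(cfg, genes, truth, chrom_sizes)
        prom = ps.truth[ps.truth["kind"] == "promoter"]
        x = truth.loc[prom["coupled_gene"], "lfc_D0vsD28"].to_numpy()
        y = prom["acc_lfc_D0vsD28"].to_numpy()
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05

    def test_d0_boost_raises_global_accessibility(self):
        cfg = sim.SimConfig(seed=2)
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        ps = sim.gen_peaks(cfg, genes, truth, chrom_sizes)
        shared = (ps.truth["class"] == "D0&D14&D28") & (ps.truth["kind"] == "background")
        sub = ps.counts[shared.to_numpy()]
        assert sub["D0_atac"].mean() > sub["D28_atac"].mean()


class TestFragments:
    def setup_ps(self, cfg):
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        return sim.gen_peaks(cfg, genes, truth, chrom_sizes), chrom_sizes

    def test_sub100_fraction_matches_weight(self):
        cfg = small_cfg()
        ps, chrom_sizes = self.setup_ps(cfg)
        frags = sim.gen_fragments(cfg, ps.peak_sets, chrom_sizes, n_fragments=60_000)
        sizes = frags["end"] - frags["start"]
        assert (sizes < 100).mean() == pytest.approx(cfg.fragment_weights[0], abs=0.03)

    def test_background_rate_bounded(self):
        cfg = small_cfg(fragment_background_rate=0.05)
        ps, chrom_sizes = self.setup_ps(cfg)
        frags = sim.gen_fragments(cfg, ps.peak_sets, chrom_sizes, n_fragments=30_000)
        d0 = frags[frags["sample"] == "D0"]
        from intervaltree import IntervalTree

        trees = {}
        for p in ps.peak_sets["D0"]:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start - 400, p.end + 400)
        mids = ((d0["start"] + d0["end"]) // 2).to_numpy()
        outside = sum(
            1
            for c, m in zip(d0["chrom"], mids)
            if c not in trees or not trees[c][int(m)]
        )
        assert outside / len(d0) <= cfg.fragment_background_rate + 0.02

    def test_determinism(self):
        cfg = small_cfg()
        ps, chrom_sizes = self.setup_ps(cfg)
        f1 = sim.gen_fragments(cfg, ps.peak_sets, chrom_sizes, n_fragments=5000)
        f2 = sim.gen_fragments(cfg, ps.peak_sets, chrom_sizes, n_fragments=5000)
        pd.testing.assert_frame_equal(f1, f2)


class TestMotifPlant:
    def test_rate_zero_empty_truth(self, consensus_pwm):
        cfg = small_cfg()
        genes, promoters, _ = sim.gen_annotation(cfg)
        clusters = pd.Series(1, index=[g.gene_id for g in genes])
        out, truth = sim.gen_motif_plant(cfg, [consensus_pwm], promoters, clusters)
        assert truth.empty and out == promoters

    def test_rate_one_plants_everywhere(self, consensus_pwm):
        cfg = small_cfg(motif_plant_rate={(6, "M1"): 1.0})
        genes, promoters, _ = sim.gen_annotation(cfg)
        clusters = pd.Series(6, index=[g.gene_id for g in genes])
        out, truth = sim.gen_motif_plant(cfg, [consensus_pwm], promoters, clusters)
        assert set(truth["gene_id"]) == set(promoters)

    def test_planted_scores_beat_background(self, consensus_pwm):
        from atacrna import motifs as mo

        cfg = small_cfg(motif_plant_rate={(6, "M1"): 1.0})
        genes, promoters, _ = sim.gen_annotation(cfg)
        clusters = pd.Series(6, index=[g.gene_id for g in genes])
        out, truth = sim.gen_motif_plant(cfg, [consensus_pwm], promoters, clusters)
        lo = mo.log_odds(consensus_pwm)
        enc = {"A": 0, "C": 1, "G": 2, "T": 3}

        def word_score(word):
            return sum(lo[i, enc[b]] for i, b in enumerate(word))

        planted_scores = []
        for _, r in truth.head(100).iterrows():
            site = r["site"] if r["strand"] == "+" else mo.reverse_complement(r["site"])
            planted_scores.append(word_score(site))
        rng = np.random.default_rng(0)
        L = len(consensus_pwm)
        bg_scores = []
        for _ in range(2000):
            w = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
            bg_scores.append(word_score(w))
        assert np.median(planted_scores) >= np.percentile(bg_scores, 99)


class TestEnhancerSnps:
    def test_enhancer_fraction_realised(self):
        cfg = sim.SimConfig(seed=9, enhancer_fraction=0.6)
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        ps = sim.gen_peaks(cfg, genes, truth, chrom_sizes)
        enh, _ = sim.gen_enhancer_db_and_snps(cfg, ps.truth, chrom_sizes)
        from atacrna.atac import overlap_fraction
        from atacrna.io import GenomicInterval

        d0 = ps.truth[ps.truth["class"] == "D0"]
        d0_iv = [
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in d0.iterrows()
        ]
        frac, _, _ = overlap_fraction(d0_iv, enh)
        assert frac == pytest.approx(0.6, abs=0.03)

    def test_infinite_odds_concentrates_snps(self):
        cfg = sim.SimConfig(seed=10, snp_odds=1e9, n_snps=300)
        genes, _, chrom_sizes = sim.gen_annotation(cfg)
        _, truth = sim.gen_counts(cfg, genes)
        ps = sim.gen_peaks(cfg, genes, truth, chrom_sizes)
        _, snps = sim.gen_enhancer_db_and_snps(cfg, ps.truth, chrom_sizes)
        target = ps.truth[ps.truth["class"] == "D28"]
        starts = target["start"].to_numpy()
        ends = target["end"].to_numpy()
        chroms = target["chrom"].to_numpy()
        inside = sum(
            bool(np.any((chroms == s.chrom) & (starts <= s.start) & (s.start < ends)))
            for s in snps
        )
        assert inside / len(snps) > 0.95


def test_biotype_fractions_cover_lncrna_classes():
    assert set(sim.DEFAULT_BIOTYPE_FRACTIONS) == {"protein_coding"} | set(LNCRNA_BIOTYPES)
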