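import itertools

import numpy as np
import pandas as pd
import pytest

from atacrna import atac
from atacrna.io import GeneModel, GenomicInterval
from atacrna.simulate import SimConfig, sample_fragment_sizes


def frag_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "strand"])


class TestTn5Shift:
    def test_offsets(self):
        frags = frag_df([("chr1", 100, 200, "s", "+"), ("chr1", 100, 200, "s", "-")])
        out = atac.tn5_shift(frags)
        assert out.loc[0, "start"] == 104  # plus-strand cut shifted +4
        assert out.loc[1, "end"] == 195  # minus-strand cut shifted -5

    def test_double_shift_raises(self):
        frags = frag_df([("chr1", 100, 200, "s", "+")])
        out = atac.tn5_shift(frags)
        with pytest.raises(ValueError, match="already"):
            atac.tn5_shift(out)

    def test_missing_strand_left_unshifted(self):
        frags = frag_df([("chr1", 100, 200, "s", ".")])
        out = atac.tn5_shift(frags)
        assert out.loc[0, "start"] == 100 and out.loc[0, "end"] == 200


class TestSizeHistogram:
    def test_unimodal_input_one_mode(self):
        rng = np.random.default_rng(0)
        sizes = rng.normal(180, 20, 5000).astype(int)
        frags = pd.DataFrame(
            {"chrom": "c", "start": 0, "end": sizes, "sample": "s"}
        )
        hist = atac.size_histogram(frags)
        assert len(hist.modes) == 1
        assert atac.round_to(hist.modes[0]) == 180

    def test_default_mixture_modes(self):
        """The default nucleosome mixture yields the mononucleosome mode at
        200 bp and the dinucleosome mode at 440 bp (nearest 10 bp)."""
        cfg = SimConfig(seed=1)
        rng = cfg.rng(99)
        sizes = sample_fragment_sizes(cfg, 200_000, rng).astype(int)
        frags = pd.DataFrame({"chrom": "c", "start": 0, "end": sizes, "sample": "s"})
        hist = atac.size_histogram(frags)
        modes = atac.nucleosome_modes(hist)
        assert modes[0] == 200
        assert modes[1] == 440


class TestMergeConsensus:
    def test_gap_below_threshold_merges(self):
        sets = {"D0": [GenomicInterval("c", 100, 200)],
                "D14": [GenomicInterval("c", 250, 300)]}
        (peak,) = atac.merge_consensus(sets)
        assert (peak.interval.start, peak.interval.end) == (100, 300)
        assert peak.present_in == {"D0", "D14"}

    def test_gap_above_threshold_stays_split(self):
        sets = {"D0": [GenomicInterval("c", 100, 200), GenomicInterval("c", 350, 400)]}
        peaks = atac.merge_consensus(sets)
        assert len(peaks) == 2

    def test_gap_exactly_100_merges(self):
        sets = {"D0": [GenomicInterval("c", 100, 200)],
                "D14": [GenomicInterval("c", 300, 400)]}
        assert len(atac.merge_consensus(sets)) == 1

    def test_different_chromosomes_never_merge(self):
        sets = {"D0": [GenomicInterval("c1", 100, 200)],
                "D14": [GenomicInterval("c2", 210, 300)]}
        assert len(atac.merge_consensus(sets)) == 2

    def test_order_invariance_and_idempotence(self):
        rng = np.random.default_rng(4)
        ivs = [
            GenomicInterval("c", int(s), int(s) + int(rng.integers(50, 300)))
            for s in rng.integers(0, 100_000, 200)
        ]
        sets1 = {"D0": ivs[:100], "D14": ivs[100:]}
        sets2 = {"D0": ivs[:100][::-1], "D14": sorted(ivs[100:], key=lambda p: -p.start)}
        out1 = atac.merge_consensus(sets1)
        out2 = atac.merge_consensus(sets2)
        key = lambda pks: [(p.interval.chrom, p.interval.start, p.interval.end,
                            tuple(sorted(p.present_in))) for p in pks]
        assert key(out1) == key(out2)
        # idempotence: remerging the merged intervals changes nothing
        again = atac.merge_consensus(
            {"D0": [p.interval for p in out1]}
        )
        assert [(p.interval.start, p.interval.end) for p in again] == [
            (p.interval.start, p.interval.end) for p in out1
        ]
        # pairwise separation of consensus peaks exceeds the merge gap
        by_chrom = sorted((p.interval.start, p.interval.end) for p in out1)
        gaps = [s2 - e1 for (_, e1), (s2, _) in zip(by_chrom, by_chrom[1:])]
        assert all(g > 100 for g in gaps)


class TestVenn:
    def test_disjoint_and_identical_sets(self):
        disjoint = {
            "D0": [GenomicInterval("c", 0, 100)],
            "D14": [GenomicInterval("c", 1000, 1100)],
            "D28": [GenomicInterval("c", 2000, 2100)],
        }
        venn = atac.venn_categories(atac.merge_consensus(disjoint)).set_index("subset")
        assert venn.loc["D0", "count"] == 1
        assert venn.loc["D0&D14&D28", "count"] == 0

        same = {tp: [GenomicInterval("c", 0, 100)] for tp in ("D0", "D14", "D28")}
        venn2 = atac.venn_categories(atac.merge_consensus(same)).set_index("subset")
        assert venn2.loc["D0&D14&D28", "count"] == 1
        assert venn2["count"].sum() == 1

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(9)
        sets = {
            tp: [
                GenomicInterval("c", int(s), int(s + 150))
                for s in rng.integers(0, 500_000, 300)
            ]
            for tp in ("D0", "D14", "D28")
        }
        consensus = atac.merge_consensus(sets)
        venn = atac.venn_categories(consensus)
        assert venn["count"].sum() == len(consensus)
        assert abs(venn["percent"].sum() - 100) <= 4  # integer rounding slack


class TestAnnotate:
    def make_peak(self, chrom, mid):
        return atac.ConsensusPeak(GenomicInterval(chrom, mid - 50, mid + 50), {"D0"})

    def test_promoter_window(self, toy_genes):
        pk = self.make_peak("chr1", 10000 - 500)  # 500 bp upstream of + TSS
        atac.annotate_peaks([pk], toy_genes)
        assert pk.category == "promoter-TSS"
        assert pk.nearest_gene == "GC1" and pk.dist_to_tss == -500

    def test_minus_strand_promoter(self, toy_genes):
        pk = self.make_peak("chr1", 52000 + 500)  # upstream of the - strand TSS
        atac.annotate_peaks([pk], toy_genes)
        assert pk.category == "promoter-TSS"
        assert pk.dist_to_tss == -500  # strand-oriented: upstream is negative

    def test_intron_and_intergenic(self, toy_genes):
        intron = self.make_peak("chr1", 12500)  # inside GC1, between exons
        far = self.make_peak("chr1", 200000)
        atac.annotate_peaks([intron, far], toy_genes)
        assert intron.category == "intron"
        assert far.category == "intergenic"

    def test_exon_beats_intron(self, toy_genes):
        pk = self.make_peak("chr1", 10500)  # mid inside first exon of GC1
        atac.annotate_peaks([pk], toy_genes)
        # promoter window [9000,10100) does not cover 10500; exon does
        assert pk.category == "exon"

    def test_categories_partition(self, toy_genes):
        rng = np.random.default_rng(2)
        peaks = [self.make_peak("chr1", int(m)) for m in rng.integers(100, 250000, 300)]
        atac.annotate_peaks(peaks, toy_genes)
        assert all(p.category in atac.CATEGORY_PRIORITY for p in peaks)

    def test_empty_annotation_all_intergenic(self):
        pk = self.make_peak("chr1", 5000)
        atac.annotate_peaks([pk], [])
        assert pk.category == "intergenic"


class TestDiffAccessibility:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, 200)
        counts = pd.DataFrame({"a": base, "b": base})
        res = atac.diff_accessibility(counts, ["a"], ["b"])
        assert res["significant"].sum() == 0
        assert res.attrs["exploratory"]

    def test_threshold_is_strict(self):
        res = pd.DataFrame(
            {"peak_id": ["p1"], "comparison": "x", "base_mean": [10.0],
             "log2fc": [1.5], "p": [0.001], "q": [0.001]}
        )
        sig = (np.abs(res["log2fc"]) > 1.5) & (res["p"] < 0.05)
        assert not sig.iloc[0]  # |log2FC| = 1.5 exactly does not qualify

    def test_planted_eightfold_recovered(self):
        rng = np.random.default_rng(5)
        n = 500
        mu = np.full(n, 300.0)
        lfc = np.zeros(n)
        lfc[:100] = 3.0
        r = 1 / 0.05
        a = rng.negative_binomial(r, r / (r + mu))
        b = rng.negative_binomial(r, r / (r + mu * 2.0**lfc))
        counts = pd.DataFrame({"a": a, "b": b})
        res = atac.diff_accessibility(counts, ["a"], ["b"])
        assert res["significant"][:100].mean() >= 0.9

    def test_all_zero_peak_excluded(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [0, 12]}, index=["z", "nz"])
        res = atac.diff_accessibility(counts, ["a"], ["b"])
        assert list(res["peak_id"]) == ["nz"]


class TestOverlap:
    def test_fraction_and_counts(self):
        q = [GenomicInterval("c", i * 1000, i * 1000 + 100) for i in range(4)]
        db = [GenomicInterval("c", 0, 150), GenomicInterval("c", 1050, 1060)]
        frac, n, total = atac.overlap_fraction(q, db)
        assert (frac, n, total) == (0.5, 2, 4)

    def test_empty_db(self):
        q = [GenomicInterval("c", 0, 10)]
        assert atac.overlap_fraction(q, [])[0] == 0.0

    def test_printed_overlap_percent(self):
        # 62,250 of 103,989 D0-specific OCRs prints as 60%
        assert atac.overlap_percent(62250, 103989) == 60


class TestSnpOverlap:
    def brute_force(self, peaks_by_class, snps, universe):
        """Enumerate every draw of n peaks from the universe and compare the
        marked count against the observed class."""
        def has_snp(iv):
            return any(s.chrom == iv.chrom and iv.start <= s.start < iv.end for s in snps)

        marked = [has_snp(iv) for iv in universe]
        out = {}
        for cls, peaks in peaks_by_class.items():
            x = sum(1 for iv in peaks if has_snp(iv))
            n = len(peaks)
            hits = total = 0
            for draw in itertools.combinations(range(len(universe)), n):
                total += 1
                if sum(marked[i] for i in draw) >= x:
                    hits += 1
            out[cls] = hits / total
        return out

    def test_matches_enumeration_on_toy_universe(self):
        rng = np.random.default_rng(3)
        universe = [GenomicInterval("c", int(i * 1000), int(i * 1000 + 200)) for i in range(10)]
        snps = [GenomicInterval("c", int(p), int(p) + 1)
                for p in rng.integers(0, 10_000, 6)]
        classes = {"A": universe[:4], "B": universe[4:7]}
        res = atac.snp_overlap_test(classes, snps, universe).set_index("class")
        brute = self.brute_force(classes, snps, universe)
        for cls in classes:
            assert np.isclose(res.loc[cls, "p"], brute[cls], atol=1e-12)

    def test_no_snps_all_p_one(self):
        universe = [GenomicInterval("c", i * 1000, i * 1000 + 100) for i in range(5)]
        res = atac.snp_overlap_test({"A": universe[:2]}, [], universe)
        assert (res["p"] == 1.0).all()

    def test_construction_enrichment_detected(self):
        universe = [GenomicInterval("c", i * 1000, i * 1000 + 100) for i in range(40)]
        target = universe[:10]
        snps = [GenomicInterval("c", iv.start + 5, iv.start + 6) for iv in target]
        res = atac.snp_overlap_test(
            {"target": target, "rest": universe[10:]}, snps, universe
        ).set_index("class")
        assert res.loc["target", "p"] < 1e-6
        assert res.loc["rest", "p"] == 1.0


class TestLocusMW:
    def ocrs(self):
        return [GenomicInterval("c", i * 1000, i * 1000 + 100) for i in range(3)]

    def frags_with_counts(self, counts, sample):
        rows = []
        for i, n in enumerate(counts):
            for _ in range(int(n)):
                rows.append(("c", i * 1000 + 10, i * 1000 + 60, sample, "+"))
        return frag_df(rows)

    def test_identical_counts_p_one(self):
        fa = self.frags_with_counts([5, 5, 5], "a")
        fb = self.frags_with_counts([5, 5, 5], "b")
        assert atac.locus_mw_test(fa, fb, self.ocrs()) == 1.0

    def test_fully_separated_exact_p(self):
        fa = self.frags_with_counts([1, 2, 3], "a")
        fb = self.frags_with_counts([10, 20, 30], "b")
        p = atac.locus_mw_test(fa, fb, self.ocrs(), total_a=10**6, total_b=10**6)
        assert p == pytest.approx(0.1)  # 2/20 rank assignments

    def test_normalisation_invariance(self):
        fa = self.frags_with_counts([1, 2, 3], "a")
        fb = self.frags_with_counts([10, 20, 30], "b")
        p1 = atac.locus_mw_test(fa, fb, self.ocrs(), total_a=10**6, total_b=10**6)
        p2 = atac.locus_mw_test(fa, fb, self.ocrs(), total_a=10**7, total_b=10**7)
        assert p1 == p2

    def test_too_few_ocrs_is_error(self):
        fa = self.frags_with_counts([1, 2], "a")
        with pytest.raises(ValueError, match=">= 3"):
            atac.locus_mw_test(fa, fa, self.ocrs()[:2])


def test_blacklist_subtraction():
    peaks = [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 600)]
    bl = [GenomicInterval("c", 50, 70)]
    kept = atac.subtract_blacklist(peaks, bl)
    assert [(p.start, p.end) for p in kept] == [(500, 600)]
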