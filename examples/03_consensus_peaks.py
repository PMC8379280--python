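"""Consensus open-chromatin regions: merging, Venn classes, annotation and
the fragment-size histogram.

Merges per-time-point peak calls (gap <= 100 bp), reports how many consensus
peaks are specific to each time point or shared, annotates them against the
gene models (promoter-TSS = 1 kb upstream + 100 bp downstream of the TSS),
and detects the nucleosome modes of the fragment-size distribution.
"""

from atacrna import atac
from atacrna.simulate import SimConfig, gen_annotation, gen_counts, gen_fragments, gen_peaks

cfg = SimConfig(seed=3)
genes, _, chrom_sizes = gen_annotation(cfg)
_, truth = gen_counts(cfg, genes)
ps = gen_peaks(cfg, genes, truth, chrom_sizes)

consensus = atac.merge_consensus(ps.peak_sets)
venn = atac.venn_categories(consensus)
print(f"{len(consensus)} consensus peaks")
print(venn.to_string(index=False))

atac.annotate_peaks(consensus, genes)
print("\nannotation categories:")
print(atac.category_counts(consensus).to_string())

frags = gen_fragments(cfg, ps.peak_sets, chrom_sizes, n_fragments=200_000)
hist = atac.size_histogram(frags, bin_width=10)
modes = atac.nucleosome_modes(hist, min_bp=150)
sub100 = float(((frags["end"] - frags["start"]) < 100).mean())
print(f"\nfragments < 100 bp (open chromatin): {sub100:.0%}")
print(f"nucleosome modes: mono = {modes[0]} bp, di = {modes[1]} bp")
# Sub-100 bp fragments come from open chromatin; the 200 bp and 440 bp modes
# are reads spanning one and two nucleosomes.
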