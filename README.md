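# atacrna

Integrative analysis of chromatin accessibility (ATAC-Seq) and gene
expression (RNA-Seq) across a differentiation time course, built around the
design of dopaminergic-neuron induction experiments: three stages
(pluripotent D0, neural-precursor D14, neuron D28) profiled with replicated
RNA-Seq (3/4/3 replicates) and one ATAC-Seq sample per stage.

The package is aimed at computational biologists who want the statistical
core of such a study as a tested, reusable library: every analysis stage is
an importable function, a synthetic-data generator reproduces the study's
statistical structure with known ground truth, and short narrative scripts
under `examples/` walk through each capability.

## What it computes

**Differential expression** — median-of-ratios size factors
(`s_j = median_i k_ij / (prod_j k_ij)^{1/m}`), FPKM, and a negative-binomial
Wald test per gene: method-of-moments dispersion shrunk toward a parametric
mean–dispersion trend `α(μ) = a₀ + a₁/μ`, statistic `log2FC / SE`. A gene is
a DEG when BH FDR < 0.05, linear |FC| > 4 and FPKM ≥ 1 in at least one
replicate of the comparison.

**Temporal profiles** — Ward/Euclidean hierarchical clustering of DEG
z-scored log2(FPKM+1) profiles into six archetypes; gene-set
over-representation by the exact hypergeometric upper tail
`P(X ≥ x) = Σ_{k≥x} C(K,k)C(M−K,n−k)/C(M,n)` with BH correction.

**lncRNA statistics** — biotype composition of the top-N DEGs by |FC|
(hypergeometric), lncRNA-class enrichment, and Pearson co-expression of
lncRNA–target pairs across all samples.

**ATAC intervals** — Tn5 +4/−5 offset, fragment-size histograms with
nucleosome-mode detection (open-chromatin mass < 100 bp; mono/di/tri
nucleosome modes), consensus peaks by transitive merging at gap ≤ 100 bp,
time-point Venn classes, midpoint annotation with promoter-TSS priority
(1 kb upstream + 100 bp downstream of the TSS), differential accessibility
(|log2FC| > 1.5 and p < 0.05), interval-overlap statistics, SNP-overlap
hypergeometric tests and locus-level Mann-Whitney tests.

**Integration** — Pearson correlation between accessibility log2FC and
expression log2FC over gene–peak pairs (promoter/exon/intron peaks at
p < 0.05); per-OCR signal matrices over center ± 5 kb with k-means row
grouping; strand-oriented TSS metaprofiles per expression cluster.

**Motifs** — PWM scanning of both strands with exact p-values from a
dynamic-programming convolution of per-position score distributions under a
0-order background, BH per motif across all scanned positions, hits kept at
FDR < 0.1; TF × cluster promoter-frequency matrices (FPKM and MAD filters)
and promoter-vs-enhancer motif frequencies.

## Worked example

`examples/04_integration_and_motifs.py` simulates the full study design
(2000 genes, ~10,000 peaks, planted accessibility–expression coupling of
0.45, motif sites planted in cluster-6 promoters) and runs the integrative
stages:

```
FC-FC correlation: r = 0.49 (p = 3.96e-56, n = 894 pairs)
motif hits retained at q < 0.1: 26
planted sites recovered: 21/34
```

The correlation recovers the planted coupling between promoter accessibility
change and expression change over the ~900 gene–peak pairs that pass the
accessibility p-filter (slightly above 0.45 because the filter prefers
larger accessibility changes). Motif recovery below 100% is expected — sites
are sampled from the PWM, so some carry enough mismatches to fall below the
significance threshold. `examples/03_consensus_peaks.py` prints the
consensus-peak Venn classes and the fragment-size modes:

```
fragments < 100 bp (open chromatin): 50%
nucleosome modes: mono = 200 bp, di = 440 bp
```

## Command line

A thin CLI wraps the library for end-to-end runs:

```sh
atacrna simulate --seed 1 --out sim/     # write synthetic inputs (GTF, FASTA, TSV, BED)
atacrna run --seed 1 --out report/       # simulate + run every stage, with manifest
```

Every table the pipeline writes is hashed into `manifest.json` together with
the seed and all thresholds, so any output can be reproduced exactly.
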