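# Methods

This note documents the models, parameter choices and numerical decisions
behind `atacrna`, and what the synthetic-data generator does and does not
emulate.

## Study design assumed

Three differentiation stages (D0, D14, D28). RNA-Seq is replicated (3, 4
and 3 replicates respectively); ATAC-Seq has a single deeply sequenced
library per stage. All genomic arithmetic is 0-based half-open; GTF input
(1-based inclusive) is converted at the parser boundary. Strand "." is
treated as "+" for TSS math with a warning rather than aborting a run.
The lncRNA group is the union of six GENCODE classes (lincRNA, antisense,
sense_intronic, processed_transcript, sense_overlapping, TEC); everything
else is protein_coding or flagged unknown.

## Differential expression

Normalisation is DESeq-style median-of-ratios: the reference is the
per-gene geometric mean over samples, and genes containing any zero are
excluded from the median. The NB test is a deliberate re-implementation of
the DESeq2 recipe without the IRLS GLM:

- per-gene dispersion by pooled within-group method of moments,
  `α = (σ² − μ)/μ²`, floored at 1e-8;
- a parametric trend `α(μ) = a₀ + a₁/μ` fitted by least squares over genes
  with usable moment estimates;
- shrinkage of log-dispersion toward the trend with weight 0.6;
- Wald statistic `log2FC / SE` with a 0.5 pseudo-count on group means, the
  SE from the delta method on the log of an NB group mean.

The reference distribution is Student t with effective degrees of freedom
`residual df / (1 − shrink weight)` (normal beyond df 30). The rationale:
with 3-vs-3 designs a plain normal reference is visibly anticonservative
(~0.086 empirical type-I error at nominal 0.05 in our null simulations)
because the group means and the dispersion are both estimated; a t with the
raw residual df overcorrects (~0.02) because shrinkage makes the variance
estimate much more stable than an unshrunken one. Scaling the df by the
shrinkage factor lands the empirical type-I error at 0.047–0.061 across
null simulations, which the calibration tests lock in.

Designs with no replication in either group (the ATAC comparisons) cannot
separate biological change from noise. Differential accessibility therefore
uses an *assumed* technical dispersion, default 0.05 — the standard
no-replicate practice recommended by the edgeR user guide — and flags the
output exploratory. The conservative alternative (blind
condition-as-replicate estimation with full trend shrinkage) remains
available via `assumed_dispersion=None`; note that when many regions truly
change, that mode absorbs signal into the dispersion and passes only the
most extreme peaks. The significance rule for accessibility is
|log2FC| > 1.5 AND raw p < 0.05 (strict inequalities) — raw p, not FDR,
unlike the expression rule; this asymmetry is intentional and matches the
two stated criteria.

The DEG rule is three-way per comparison: BH FDR < 0.05, linear fold-change
of normalised means strictly greater than 4 (two-sided, i.e. |log2FC| > 2),
and FPKM ≥ 1 in at least one replicate of the two compared time points. The
compiled DEG list is the union over the three comparisons. Whether the FC
threshold should apply to shrunken or raw fold-changes is genuinely open;
we apply it to the (unshrunken) Wald log2FC, since no LFC shrinkage is
performed.

`bh_fdr` is the Benjamini–Hochberg step-up with stable ties; NaN p-values
propagate with a warning and do not count toward m.

## Clustering and enrichment

DEG profiles are per-time-point replicate means of FPKM, row z-scored after
log2(x+1); constant rows become all-zero vectors and are flagged
degenerate. Clustering is agglomerative with Ward linkage on Euclidean
distance, cut at k = 6 (configurable); labels are renumbered by descending
cluster size with deterministic tie-breaks. k = 6 and Ward/Euclidean are
design choices — only "hierarchical clustering" is inherent to the method.

Gene-set enrichment is the exact hypergeometric upper tail with BH across
sets; only sets overlapping the cluster are reported. The universe is an
explicit argument; the recommended population (used throughout the
examples) is genes with max FPKM ≥ 1 in any sample — expressed genes, the
conservative standard choice.

The top-N biotype test ranks the DEGs of one comparison by absolute linear
fold-change (ties broken by smaller q then lexicographic id), and tests the
lncRNA (and coding) count among the top N against a hypergeometric draw
from all DEGs of the comparison. Using all DEGs rather than all genes as
the population is a choice; it is the conservative reading and is
configurable by passing a different table.

## ATAC intervals

Tn5 offsets are +4 (plus strand) and −5 (minus strand); on a paired-end
fragment the start is the plus-strand cut and the end the minus-strand cut.
A state flag forbids double-shifting.

Fragment-size histograms use 10 bp bins from zero, a 3-bin moving average,
and report modes as local maxima with prominence ≥ 5% of the smoothed
maximum (scipy `find_peaks`); mode positions are bin centers. Under the
default mixture the trinucleosome mode at 600 bp sits below the prominence
floor — by design the detector reports only unambiguous modes.

Consensus peaks merge the pooled per-time-point calls transitively whenever
the gap is ≤ 100 bp ("within 100 bp" read inclusively; the boundary case
merges). `present_in` records every time point contributing an overlapping
source peak (any overlap). Merging is order-invariant and idempotent, and
output peaks are pairwise separated by more than the merge gap.

Annotation is by peak midpoint with priority promoter-TSS > TTS > 5'UTR >
3'UTR > exon > intron > intergenic. Promoter-TSS is 1 kb upstream plus
100 bp downstream of the TSS, strand-oriented; the TTS window mirrors it
around the transcript end. UTR categories fire only when gene models carry
explicit UTR intervals (plain gene/exon GTFs do not, and the synthetic
annotation does not plant them). `dist_to_tss` is signed and
strand-oriented, negative upstream. An ENCODE-style blacklist filter is
provided as generic interval subtraction.

The SNP-overlap test marks universe peaks containing ≥ 1 SNP and compares
each peak class by the exact hypergeometric upper tail with BH across
classes. The universe defaults to all consensus peaks; genome bins would be
an alternative population, so the argument is explicit.

Locus-level comparisons use a two-sided Mann-Whitney U on per-OCR
fragment counts scaled per million; exact p for ≤ 8 regions per side
without ties, normal approximation otherwise, and p = 1 by convention when
the normalised vectors are completely tied. At least 3 OCRs are required.

## Integration

The FC–FC analysis joins accessibility records with p < 0.05 on peaks
annotated promoter-TSS/exon/intron to the nearest gene's expression
log2FC; each qualifying gene–peak pair contributes one point (a
best-peak-per-gene mode keeps the max-|FC| peak instead). Pearson r is
reported with its two-sided p. Because the p-filter preferentially keeps
larger accessibility changes, the measured r on synthetic data sits
slightly above the planted coupling (≈ +0.05 at coupling 0.45); the
recovery tests bound this bias.

Signal matrices count fragment midpoints in 100 bp bins over OCR center
± 5 kb, scaled per million fragments, so library depth cancels; row
grouping uses k-means (k-means++ init, 10 restarts, fixed seed). TSS
metaprofiles are per-cluster, per-sample mean coverage, strand-oriented so
upstream is always left.

## Motif analysis

Log-odds are `log2((p + ε)/(b + ε))` with ε = 1e-4 keeping zero
probabilities finite. Scores are discretised to a 1e-3-bit grid; the exact
null distribution of a word score is built by convolving per-position score
distributions under the background, so p-values are exact on the grid
(discretisation error is bounded by the grid times motif length, ~0.01
bits). Scanning covers both strands; N scores zero. The background defaults
to the 0-order, strand-symmetrised composition of the scanned set
(uniform available). BH is pooled per motif across all positions ×
sequences × strands — the broadest pool, hence the most conservative; hits
are kept at q < 0.1.

A practical consequence quantified during design: a weak 8-bp motif has a
minimum achievable p of 0.25⁸ ≈ 1.5e-5, which cannot survive BH over a
megabase of scanned promoter positions at q < 0.1 regardless of how many
sites are planted. The generator's default PWMs are therefore 12-mers with
0.9 consensus-base probability, the information scale of curated TF
matrices.

The TF × cluster matrix reports the percent of cluster genes whose promoter
carries ≥ 1 retained hit of any motif of the TF, drops TFs with max
FPKM < 1 or with median absolute deviation of the frequency (fraction
scale) < 0.05 across clusters, and orders rows by average-linkage
hierarchical clustering. Promoter-vs-enhancer frequencies treat
promoter-TSS peaks as promoters and intergenic/intron/exon/UTR peaks as
enhancers; per TF the motif maximising the summed class frequency is
reported ("most enriched" operationalised as max total frequency), with an
include-list for named non-DE exceptions.

## Synthetic-data generator

The generator is first-class, fully deterministic (every stage draws from
`default_rng([seed, stage])`; identical configs give byte-identical
outputs) and always emits truth tables sufficient to score recovery.

- **Annotation**: genes tiled on synthetic chromosomes (200 per chromosome,
  ≥ 10 kb spacing), biotypes drawn from fractions summing to 1 (default:
  70% coding, 12% lincRNA, 8% antisense, 3% sense_intronic, 4%
  processed_transcript, 2% sense_overlapping, 1% TEC). Antisense and
  sense_intronic genes are linked to the adjacent coding gene as their
  regulatory target. Promoters are 2001 bp of uniform random sequence
  centered on the TSS.
- **Counts**: six temporal archetypes expressed as log2 shifts
  (down-at-D14-staying-down; down-then-recover; down-at-D28;
  up-at-D14-settling-high; transient-D14-peak; up-at-D28), gene magnitudes
  ~ Normal(3, 0.8) log2 units truncated at 1 (median fold-change 8), a
  configurable null fraction (default 0.3) of flat genes, NB dispersion 0.1
  (Poisson at 0), lognormal library factors (σ = 0.1) and optional batch
  multipliers. The batch-to-replicate assignment is free because no single
  layout is canonical.
- **Peaks**: every coding gene gets a promoter peak present at all time
  points; background peaks are placed intergenically (gene-proximal
  accessibility is the promoter peaks' job) and partitioned into
  specific/shared classes with proportions mirroring the study's Venn
  shape (22/32/19% specific, 11% all-shared). Promoter accessibility
  log2FC (D0→D28) is a shared-latent construction:
  `acc = s·(ρ·z_expr + √(1−ρ²)·ε)` with s = 2, giving Pearson correlation ρ
  with the gene's expression log2FC (default ρ = 0.45). Counts are NB with
  dispersion 0.05 (deep single libraries), base mean 500, and a global
  ×1.2 D0 boost emulating higher pluripotent-stage accessibility.
- **Fragments**: sizes from a four-component mixture — sub-100 bp
  open-chromatin mass as 40 + Exp(20) truncated at 100 (weight 0.50), and
  Gaussian nucleosome modes at 200/440/600 bp with σ 25/40/50 (weights
  0.28/0.14/0.08). Weights were fixed from the qualitative target shape:
  most fragments sub-100 bp, clearly visible mono- and di-nucleosome
  peaks, a weak trinucleosome shoulder. Midpoints fall inside a random
  open peak of the sample's time point except a 5% uniform background.
- **Motif planting**: per-(cluster, motif) rates; sites sampled from the
  PWM, inserted on a random strand at a random offset, recorded in a truth
  table.
- **Enhancers/SNPs**: the enhancer DB covers a configurable fraction
  (default 0.6) of D0-specific peaks plus decoys; SNPs hit
  D28-specific target peaks with configurable odds against a uniform
  background placed on the complement of the target (odds 1 is exactly
  uniform, which the null-calibration tests exploit).

Desk-scale defaults (2000 genes, ~10,000 peaks) keep a full simulation
under ~2 s and the whole pipeline run well under a minute.

### What the generator does not emulate

Raw reads, alignment and duplication artifacts, GC and mappability bias,
chromatin domains and peak-width heterogeneity, isoform structure, batch
confounding beyond a scalar multiplier, and real promoter sequence
composition (promoters are uniform random, so motif-scan backgrounds are
cleaner than genomic ones). Passing recovery tests therefore demonstrates
the statistical machinery is correct and calibrated under the assumed
generative model, not that biological preprocessing issues are handled.

## Calibration-test design sizes

The SNP-overlap null calibration uses a 10,000-peak universe and 2,000
SNPs so that the exact hypergeometric p-value lattice is fine enough
(maximum point mass ~0.03) for a Kolmogorov–Smirnov uniformity check over
200 replicates to be meaningful; with small counts the discrete
superuniform null would fail KS for reasons unrelated to the test. The
motif background calibration uses the fact that under the global null BH's
FDR bound equals the probability of any retained hit, so the count of
seeds (of 20) with ≥ 1 hit is Binomial(20, ≤ 0.1).

## Known limitations

- The NB test is calibrated for ranked log2FC/q consumption, not DESeq2
  bit-identity; a cross-check test asserts strong rank agreement with
  DESeq2 on mixed null/signal data.
- Single-replicate differential accessibility is exploratory by
  construction; its p-values inherit the assumed-dispersion choice.
- The FC–FC correlation carries a small positive selection bias from the
  significance filter (quantified above).
- Exact Mann-Whitney p-values require tie-free data; ties fall back to the
  normal approximation (full tie → p = 1 convention).
- Motif q-values depend on the BH pooling scope; per-sequence pooling gives
  less conservative hits and is available as an option.
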