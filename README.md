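# orgdriver

Multi-omics analysis tools for cell-type-enriched intestinal organoid
studies: absolute quantification of proteome and transcriptome against
spike-in standards, translation-efficiency (protein-per-mRNA) statistics,
permutation-FDR differential testing, detection of coordinately regulated
topologically associating domains (TADs), and — at the core — an iterative
motif-regression procedure that identifies the transcription factor whose
binding motif drives genome-wide chromatin dynamics.

The package is aimed at computational biologists who have condition ×
replicate matrices (iBAQ/LFQ protein intensities, RNA-seq counts, peak-level
ATAC/ChIP counts), peak and TAD intervals, a genome, and a PWM database, and
who want the full inference chain as tested, reusable functions. A
synthetic-data module generates complete studies with planted ground truth
(true copy numbers, a causal "driver" PWM, coordinated TADs, ratio-shifted
genes), so every stage can be validated end to end without external data.

## The methods in brief

**Absolute quantification.** Stage 1 fits per-sample OLS of
log10(amount) on log10(intensity) over a UPS2-style spike-in panel in the
unfractionated proteome run; stage 2 maps the deep fractionated intensities
onto stage-1 absolute abundances through a second log–log regression on
shared proteins. mRNA copies come from a single ERCC-anchored regression.
Per-sample fitting makes copy numbers invariant to rescaling any sample.

**Protein-per-mRNA ratios.** For each gene and condition the ratio is the
median over all replicate pairs (i, j) of protein_i / mRNA_j. A t-test on
Fisher-transformed Pearson correlations of replicate log-ratio vectors
(within- vs between-condition pairs) tests for global translation/degradation
differences; a Welch-form test on pairwise log ratios with degrees of freedom
restricted to the biological replicate count, (n_A−1)+(n_B−1), tests
individual genes, with Benjamini–Hochberg FDR. Genes with FDR < 0.05 and
fold change > 3 in both comparison arms (same direction) are flagged.

**Differential testing.** A moderated statistic d = Δmean / (se + s₀) with a
label-permutation FDR: q(feature) is the mean permuted count of
|d_perm| ≥ |d| over the observed count of |d_obs| ≥ |d|, monotonized. For
count matrices, median-of-ratios size factors and pseudocount-shrunken
log2 fold changes, log2((μ_A + c)/(μ_B + c)).

**TAD coordination.** Per TAD (≥ 20 peaks), percentage agreement = share of
member peaks whose fold-change sign matches the sign of the TAD's mean fold
change. 100 genome-wide shuffles of the fold changes give an empirical FDR
and a significance cutoff.

**Motif-driver selection.** Candidate PWMs are restricted to motifs whose
linked TFs change in protein expression at FDR < 0.01; each motif's
best-match log-odds score (both strands) is computed under every
significantly changing peak; 10-fold cross-validated LASSO pre-selects
predictors of the peak log2 fold changes; then, iteratively: fit a random
forest, take the motif with the highest out-of-bag permutation importance
(%IncMSE), stop if a single-motif forest has out-of-bag R² ≤ 0, otherwise
subtract its out-of-bag predictions from the response and repeat. The whole
selection runs five times with independent seeds; only motifs selected every
time are reported, each labeled with its most significantly changing TF.

**Enrichment.** Preranked GSEA (weighted Kolmogorov–Smirnov enrichment
score) with a gene-set permutation null, NES normalization and the standard
NES-ratio FDR.

## Worked example

```python
import numpy as np
import orgdriver as od

design = od.SampleDesign(seed=42)          # CV / ENR / EN, 3 replicates each
land = od.simulate_regulatory_landscape(design, seed=42)

fc = od.count_fold_changes(land.counts, design, ("EN", "ENR"), seed=1)
tf_diff = od.permutation_fdr_ttest(
    np.log2(land.tf_expression),
    design.samples_of("EN"), design.samples_of("ENR"), seed=2).table

from orgdriver.motif_driver_selection import peak_sequences, score_peaks, select_drivers
seqs = peak_sequences(land.peaks, land.genome.chromosomes)
scores = score_peaks(seqs, land.motifs, peak_ids=list(land.peaks.name))
res = select_drivers(scores, fc.table, land.tf_map, tf_diff,
                     repeats=5, n_trees=500, seed=7)
print(res.final)
print(res.table.round(3).to_string(index=False))
```

Output:

```
['motif001']
   motif  order  pct_inc_mse  sd_inc_mse  single_r2  stability  correlation    tf
motif001    1.0      183.181      28.178      0.484          5        0.629 TF001
```

The generator planted `motif001` as the causal driver of the EN-condition
peak fold changes; the selection recovers it as the only motif stable across
all five repeats. Permuting its scores raises the forest's out-of-bag MSE by
183% (±28% sd over trees), a single-motif forest explains 48% of the
fold-change variance out-of-bag, and its normalized best-match score
correlates at r = 0.63 with the peak log2 fold changes under significant
peaks. No decoy motif survives the stability filter.

The same stages are available from the shell:

```bash
orgdriver simulate --outdir sim --seed 3
orgdriver quantify --unfractionated sim/protein_unfractionated.tsv \
    --fractionated sim/protein_fractionated.tsv --counts sim/mrna_counts.tsv \
    --protein-spikeins sim/protein_spikeins.tsv --ercc-spikeins sim/ercc_spikeins.tsv \
    --outdir quant
orgdriver ratios --protein-copies quant/protein_copies.tsv \
    --mrna-copies quant/mrna_copies.tsv --outdir ratios
orgdriver diff --matrix sim/peak_counts.tsv --layer peaks --seed 1 --out peak_fc.tsv
orgdriver diff --matrix sim/tf_expression.tsv --layer protein --seed 1 --out tf_diff.tsv
orgdriver tads --h3k27ac-fc peak_fc.tsv --peaks sim/peaks.bed --tads sim/tads.bed --out tads.tsv
orgdriver motifs --peaks sim/peaks.bed --fc peak_fc.tsv --genome sim/genome.fa \
    --pwms sim/motifs.jaspar --tf-map sim/motif_tf_map.tsv --tf-diff tf_diff.tsv --out motifs.tsv
orgdriver gsea --rnk ranking.rnk --gmt sim/gene_sets.gmt --out gsea.tsv
```

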