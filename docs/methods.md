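# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a user auditing results will want to know.

## Study design and the synthetic generator

The default design mirrors a three-condition organoid differentiation
experiment — a stem-cell-enriched culture ("CV"), the reference culture
("ENR") and an enterocyte-enriched culture ("EN") — with three biological
replicates each. The last condition plays the "differentiated" role: planted
expression changes, driver-motif effects and TF shifts all act in EN
relative to the others.

**Expression model.** True protein copies per cell are log-normal,
10^N(4, 1); protein-per-mRNA ratios are 10^N(2.5, 0.5), giving mRNA copies
in the tens — both in the range reported for deep mammalian proteome/
transcriptome studies. Measured intensity is gain × copies × e^ε with
ε ~ N(0, σ), σ chosen so the replicate coefficient of variation equals
`noise_cv` (default 0.2, a typical LFQ replicate CV). Spike-ins obey the
same gain, which is what makes absolute calibration possible. mRNA counts
are negative-binomial with mean capture × copies (capture 20 counts per
molecule, emulating a ~30M-read bulk library) and dispersion 20 (replicate
CV ≈ 22%). A 20% subset of genes changes 4-fold in EN at both layers
(transcriptionally driven change); a disjoint 5% subset shifts its
protein/mRNA ratio 8-fold in the two non-EN conditions, same direction in
both — the translation-efficiency signal the ratio tests must find.

**Missingness.** Low intensities are censored with probability following a
logistic curve in log10 intensity around the `missing_rate` quantile of the
intensity distribution: 0.90 far below the threshold, 0.05 far above, width
0.3 log10 units. The 5% floor means even bright proteins occasionally drop
out, and ~10% of sub-threshold values survive; both features matter for how
far detection-limit imputation can be validated (below).

**Regulatory landscape.** TADs tile the 2 Mb genome without overlap; peaks
(400 bp) are spaced evenly inside TADs so the geometry is valid by
construction (requests that would force overlapping peaks are rejected).
One driver PWM is embedded — one instance per designated peak, random
offset and strand, base sampled per position from the PWM rows — in 30% of
peaks; those peaks get a +2 log2 negative-binomial mean shift in EN. Decoy
PWMs are embedded in random peaks independently of any fold change. A
ceil(5%) subset of TADs imposes a shared fold-change sign (±1 log2 unit) on
95% of member peaks. The driver's TF is planted 4-fold up in EN in the TF
protein table so it clears the FDR < 0.01 expression filter by
construction; ~40% of decoy TFs are also differential (1.5–2.5 log2,
random sign) so the filter leaves a genuine multi-candidate problem.
Promoter instances of the driver motif (planted in 60% of the designated
"up" genes) use the consensus sequence: the promoter-fraction statistic
thresholds at consensus-score − 2 bits, and sampled instances with one
mismatch already fall ~4 bits below consensus for these informative PWMs.

**What the generator does not emulate.** Peptide-level inference, fraction
structure, match-between-runs artifacts, GC/length biases in counts,
spatially structured chromatin, single-cell heterogeneity, or correlated
decoy motifs (real PWM databases contain near-duplicate families; the
decoys here are independent). Passing tests therefore demonstrate the
statistical machinery under the declared error model, not robustness to
every artifact of real data.

## Absolute quantification

All regressions are ordinary least squares on log10 scale — the standard
iBAQ practice, linearizing the 4–5 decade dynamic range. Calibration is
fitted per sample; a sample-wide multiplicative change in intensities moves
only the intercept, so copy numbers are invariant to it (tested). Fits use
observed values only: imputation before calibration injects detection-limit
draws into the predictor and dilutes the stage-2 slope (observed ~0.84
versus ~1.00 without; classic errors-in-variables attenuation). At least 5
detected spike-ins spanning ≥ 2 orders of magnitude are required; a
non-positive slope is flagged as calibration failure. Zero counts yield an
undefined (missing) copy number, never zero.

## Ratio statistics

The replicate-pair ratios within a condition are dependent: with 3 + 3
replicates there are 9 pairs but only 4 independent degrees of freedom. The
per-gene test therefore uses df = (n_A − 1) + (n_B − 1) = 4 and scales the
pairwise-ratio variance by the biological replicate count (the smaller
observed layer count when values are missing, conservatively). Under a null
simulation this holds the type-I rate at 5.0%; using the pair count instead
inflates it to 22%. Genes need ≥ 2 observed replicates per layer per
condition to be tested.

This restricted-df test is deliberately conservative, and that bounds the
power of the two-arm significance filter (FDR < 0.05 and fold change > 3 in
both CV/EN and ENR/EN, same direction): at the default noise a true 8-fold
shift yields t ≈ 8 and p ≈ 10⁻³, right at the Benjamini–Hochberg threshold
for ~2,000 tests with ~100 true shifts, so per-arm power is ~0.7–0.85 and
the both-arm intersection lower; censoring additionally removes a share of
down-shifted genes from the testable set. The acceptance suite records the
measured sensitivity (~0.45–0.5 at defaults, with a false-flag rate of 0)
rather than masking the trade-off; the filter is tuned for purity, not
recall, and every flag it does raise is trustworthy.

The global translation test Fisher-transforms Pearson correlations between
replicate log-ratio vectors and t-tests within-condition against
between-condition values; correlations at ±1 are clipped at atanh(1−10⁻¹²).

## Differential testing

The moderated statistic uses a pooled-variance standard error plus a
constant s₀ = 0.1 (log2 scale) — the conventional stabilizer magnitude for
this test family; configurable. With equal group sizes, a label assignment
and its complement produce mirror-image statistics, so the permutation null
enumerates unordered partitions (9 distinct for 3v3; random draws when more
than `n_perm` exist). q-values are the mean null tail count over the
observed tail count, made monotone non-increasing in |d| (a more extreme
statistic never reports a larger q) and capped at 1. Count matrices use
median-of-ratios size factors over features with no zero count, and a
pseudocount prior (default 4) stabilizes fold changes of low-count peaks —
an explicit approximation of shrinkage-based count models, not a clone of
any of them. Imputation defaults (downshift 1.8 sd, width 0.3 sd per
sample) follow common detection-limit practice. Because ~10% of
sub-threshold intensities survive censoring, the observed distribution
keeps a thin deep tail; imputed means sit below the observed 5th percentile
(validated), not necessarily below the 1st.

## TAD coordination

Peaks are assigned to the TAD containing their midpoint. Agreement counts
zero fold changes as disagreeing (conservative) and the direction comes
from the sign of the TAD's mean fold change. Because that reference sign is
estimated from the same peaks, the null expectation of agreement exceeds
50% at small peak counts; the shuffle null (fold changes permuted across
all peaks genome-wide, TAD membership fixed; within-chromosome shuffling is
not implemented as the synthetic genome has no chromosome-scale structure)
reproduces exactly this bias, keeping the empirical FDR calibrated
(self-null flag rate ≈ 0 at the 0.05 cutoff). TADs with mean fold change
exactly zero are skipped with a log entry.

## Motif-driver selection

Best-match scores are the maximum log-odds over all offsets and both
strands, with uniform background and pseudocount 10⁻³ on the PWM rows; the
reverse strand is scored by scanning with the reverse-complement PWM
(provably identical). Scores are min-max normalized to [0, 1] per motif
before regression so importances are comparable across motifs of different
length and information content; raw log-odds are retained for reporting.

LASSO uses 10-fold cross-validation with the penalty at minimum CV error —
the less aggressive choice, deferring pruning to the forest stage.
Predictors are standardized internally; a constant response returns an
empty selection.

The iterative forest stage fits 5,000 trees by default (500 in the CLI and
the recovery experiments — at ~10–20 candidate predictors the importance
ranking is already stable at 500 trees, and a 5,000-tree run reproduces the
same selections; the library default keeps the published setting).
`min_samples_leaf=5` and `max_features=1/3` follow the R randomForest
regression defaults the procedure is modeled on. %IncMSE is computed per
tree from its out-of-bag samples — permute one predictor's OOB values,
measure the relative MSE increase — and averaged over trees, with the sd
over trees reported (error bars in the result table are 2× this sd).
"Variance explained by a single motif" is operationalized as the out-of-bag
predictions of a one-predictor forest; the loop stops, without selecting,
when that forest's out-of-bag R² falls at or below a stopping tolerance of
0.01. The tolerance is not zero because best-match scores are maximum
statistics over a shared sequence: inserting one motif's site into a peak
perturbs every other motif's maximum by a sliver, so unrelated motifs carry
a crosstalk-level trace of the response (|r| ≲ 0.03 here) that a forest can
genuinely, if uselessly, predict. Requiring at least 1% of residual
variance places the cut above that floor and well below any driver-level
signal (single-motif R² ≈ 0.05–0.11 in the synthetic studies). Each of the
five stability repeats
re-seeds both the CV folds and the forests; only motifs selected in all
five enter the final set. Under response permutation the procedure returns
the empty set in ≥ 95% of runs — its internal false-discovery control.

## Enrichment

The enrichment score is the running-sum extremum with hit increments
|metric|^p (p = 1 by default; p = 0 reduces to the classic KS form) and
miss decrements 1/(N − N_h). Ties between equal-magnitude positive and
negative extrema resolve to the positive one. Ranking ties break by gene id
(stable). The null distribution draws random same-size gene sets from the
ranked universe (the null depends only on set size, so it is cached per
size and computed in memory-bounded chunks); NES divides by the sign-matched
mean |null ES|, the nominal p is add-one corrected, and the FDR is the
pooled null-NES tail fraction over the observed tail fraction, sign-resolved,
monotonized and capped at 1. All-zero-weight sets fall back to equal
weights rather than dividing by zero.

## Problem sizes

The recovery experiments run at 2,000 peaks, 50 motifs (1 driver), 2,000
genes, 200 TADs and three conditions × three replicates; calibration checks
use 200–300 Monte-Carlo repetitions of small matrices. These sizes give
Monte-Carlo standard errors comfortably inside the asserted margins while
keeping a full validation run in minutes on one CPU.

## Known limitations

* The pseudocount fold-change shrinkage approximates, but does not
  reproduce, dedicated count-model shrinkage estimators.
* The ratio-change filter is purity-oriented; see the power discussion
  above before using it for recall-sensitive screens.
* The GSEA FDR follows the standard NES-ratio bookkeeping and can be
  conservative with few gene sets.
* Decoy motifs are generated independently; correlated motif families in
  real databases will lower stability-selection specificity relative to the
  synthetic benchmark.
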