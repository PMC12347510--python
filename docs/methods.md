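# Methods

This note documents the statistical procedures implemented in `lenssig`,
their defaults, the design decisions that were genuinely open, and the
limits of what the synthetic-data tests demonstrate.

## Study design and data model

The package targets a two-class bulk expression contrast — regenerative
wound healing (WH) versus fibrosis (F) after lens injury — measured over
3 days with 3 biological replicates per condition and day: 18 samples in
total. Expression arrives as a genes × samples FPKM matrix
(`ExpressionMatrix`), with per-sample condition and day labels. Fibrosis
is the positive class (coded 1) in every classifier.

Two parallel matrices are maintained through a run: TPM-derived
`log2(TPM+1)` values drive all modeling, while raw FPKM values are used
for the pooled fold changes and visualization exports, since FPKM is the
scale on which such results are conventionally reported.

## Normalization

`fpkm_to_tpm` rescales each sample column to sum to 10⁶
(`TPM = FPKM / Σ FPKM × 1e6`), removing residual depth differences; it is
rank-preserving within a sample and idempotent up to rescaling. An
all-zero sample column is an error, not a silent NaN. `log_transform`
applies `log2(x + offset)` with default offset 1 — the standard
variance-stabilizing choice that maps zeros to zero; the offset is
configurable, and the unit tag records the full lineage (e.g.
`log2(TPM+1)`) so downstream stages can refuse the wrong scale.

## Train/holdout split

`make_holdout_split` draws 5 samples per class (seeded, stratified by
condition only — a 5-per-class draw cannot be balanced over three days of
three replicates), leaving 4 + 4 for training. Everything downstream of
the split — the univariate screen included — sees only training samples;
the holdout surfaces exclusively in evaluation. A dedicated test asserts
that no holdout sample identifier appears in any selection artifact, and a
label-permutation suite checks that the pipeline's holdout AUC collapses
to chance when the training labels carry no information.

The screen runs on training samples only. The alternative — screening on
all 18 samples before the split — is a form of selection leakage: screen
false positives would then correlate with holdout labels, and the
permutation guard would (correctly) flag it.

## Univariate screen

Per gene, Welch's unequal-variance t-test with the Welch–Satterthwaite
degrees of freedom, two-sided, no multiplicity correction (the screen is a
model-selection pre-filter, not an inference). A gene is kept iff
|mean_WH − mean_F| ≥ δ (default 1, on the TPM scale — the literal protocol
reading; a log2-scale switch exists) and p ≤ α (default 0.05, computed on
`log2(TPM+1)` for variance stability). Genes with zero variance in both
groups get p = NaN and are dropped with a logged warning.

Under the null (no planted effects, 2000 genes, 9 v 9), the fraction of
genes with p ≤ 0.05 is empirically within [0.03, 0.07] — the t
approximation is adequately calibrated at this n — and the kept set is
monotone in both (δ, α).

## Bootstrap-LASSO stability selection

200 stratified subsamples of 75% of the training samples, drawn without
replacement. Within each subsample, genes are z-scored and an L1-penalized
logistic regression is fit; a gene counts as *selected* when its
coefficient is nonzero. The penalty grid is data-driven: 100 log-spaced
values from λ_max (the KKT-derived smallest penalty with empty support,
`max_j |x_jᵀ(y − ȳ)|/n`) down three decades. Because the paper-level
protocol does not say how the penalty is set inside a bootstrap, each
bootstrap chooses λ by a fast 3-fold stratified CV (binomial deviance)
over a 5-point sub-grid of the shared grid — "selected" then means
"nonzero at that bootstrap's own operating point". Genes selected in ≥50%
of bootstraps form the stable set; a 3-fold cross-validated LASSO over the
full grid is then refit on the stable genes, and the final panel is the
nonzero support at the deviance-minimizing λ (ties resolved toward the
sparser model).

Numerical notes: the liblinear solver is run at tol 1e-6 — at looser
tolerances it leaves spurious near-zero coefficients that corrupt the
"selected = nonzero" rule — and with a fixed `random_state`, since
liblinear otherwise carries global RNG state between calls and breaks
run-to-run determinism. The bootstrap loop calls the solver through
scikit-learn's low-level liblinear entry point (identical coefficients,
~3.5× less per-fit overhead), falling back to the estimator API if that
private symbol moves.

An empty stable set is a legitimate outcome (it is the norm under permuted
labels): the track then reports no panel and predicts 0.5 everywhere, so
its holdout AUC is 0.5 by the tie convention.

## SVM track

One linear soft-margin SVM (C = 1, fixed, not tuned — consistent with a
fixed-hyperparameter protocol at n = 8) on the z-scored screened matrix
ranks genes by |w|; ties break lexicographically. The top 5 are probed
with permutation importance and genes whose mean AUC drop is not strictly
positive are pruned. The surviving panel trains an RBF-kernel SVM
(γ = `scale`), with Platt-sigmoid probability calibration fit 3-fold on
training data only (isotonic is infeasible at n = 8). Decision values are
negated from libsvm's convention so that negative predicts fibrosis and
positive predicts wound healing; calibrated P(F) and the decision value
order samples identically.

## Random-forest track

500 trees, 50% of features considered at each split, unlimited depth,
bootstrap resampling on; Gini importances are scikit-learn's
impurity-decrease values, normalized to sum to one. The top 10 genes by
Gini are probed with permutation importance; the final panel is the top 3
by Gini among those confirmed (positive drop), and a reduced forest refit
on the panel supplies holdout probabilities (fraction of trees voting F).
If fewer than 3 genes are confirmed the panel shrinks with a warning.

## Permutation importance (shared engine)

Computed on training data only, never the holdout: the classifier is fit
once per stratified 3-fold split, and the baseline is the fold-averaged
out-of-fold AUC (fold-averaged rather than pooled, so per-fold decision
scales cannot distort it). Each probed gene's values are then shuffled
across samples (100 seeded shuffles; other genes fixed) and importance is
the mean drop in that AUC. A constant gene, or one outside the model's
feature set, has importance exactly 0.

**Degenerate probes.** With several mutually redundant strong features the
out-of-fold AUC sits at 1.0 and stays there under every permutation of
every probed gene: each drop is exactly 0 with zero spread, and the strict
"retain ⟺ drop > 0" rule would discard an entire, perfectly
discriminative panel. The engine therefore treats an all-flat probe as
carrying no evidence against any gene and retains the probed panel
unchanged (logged). An individually flat gene among informative drops is
still pruned — that is the engine's analogue of excluding the one
candidate whose permutation shows no AUC drop. This ceiling is an
intrinsic property of permutation importance under feature redundancy at
small n, not an implementation artifact.

## Evaluation

AUC is the all-pairs probability P(score_F > score_WH) + ½P(tie),
identical to the trapezoidal ROC area and Mann–Whitney U/(n₁n₂); the test
suite checks it against a brute-force pair enumeration exactly. Confusion
matrices threshold P(F) at 0.5. Per-gene ROC uses the gene's expression as
the score and reports max(AUC, 1−AUC) with an orientation flag (the
granularity at 5 + 5 holdout samples is 1/25 = 0.04). Pooled fold changes
are `log2(mean_F / mean_WH)` on FPKM over all 9 + 9 samples, with the
offset added inside the ratio only when a pooled mean is exactly zero
(flagged); their p-values are Welch tests on per-sample `log2(FPKM+1)`,
and 95% CIs on the per-condition `log2(FPKM+1)` means use the t quantile —
the conventional construction where none is prescribed. PCA (two
components on mean-centered log2 expression) is provided for QC.

## Per-gene set enrichment

For a candidate gene, all other genes are ranked by Pearson correlation
with the candidate across all 18 samples — the common per-gene
co-expression GSEA idiom; the ranking metric is configurable
(signal-to-noise between conditions is the alternative). The weighted-KS
running sum increments at set members by |r|^p / Σ_hits |r|^p (p = 1 by
default; p = 0 reduces exactly to the classic unweighted KS statistic) and
decrements at non-members by 1/(N − N_hits), so it always terminates at 0;
ES is the signed extremum (positive preferred on exact-magnitude ties) and
the leading edge is the set members at or before it (at or after, for
negative ES). Sets with fewer than 5 or more than 500 members in the
ranked list are skipped.

With 18 samples, phenotype permutation is not viable, so the null is
**gene-set permutation**: 1000 random same-size sets, vectorized over
permutations. NES = ES / mean(|null ES| of the same sign); FDR is the
standard tail-ratio estimate on the pooled null NES distribution, clipped
to [0, 1] and set to 1 with a warning when a null tail is degenerate.
Results are filtered to NES > 0 and sorted by FDR, matching the pipeline's
reporting convention. Gene sets are supplied as GMT files; no live
database queries (versions drift), and set members absent from the ranked
list are simply not hits.

## ΔΔCt quantification

Technical replicates are averaged to one Ct per (experiment, condition,
gene); ΔCt = Ct_target − Ct_reference (GAPDH by default) removes input
amount; ΔΔCt subtracts the baseline condition's mean ΔCt, and the fold
change is 2^−ΔΔCt (amplification efficiency fixed at 2; no standard-curve
correction). Folds are summarized as mean ± SEM over the 3 independent
experiments, and the Welch test compares the per-experiment ΔCt values
between conditions — the biological-replicate unit. By construction the
baseline condition's mean ΔΔCt is 0, and adding a constant to every Ct of
one experiment (a plate shift) changes nothing.

## Synthetic data generator

`generate_expression` draws per-gene log2 baselines uniformly on [0, 10],
adds a fixed log2 effect (default 3) to planted genes in their target
condition (defaults: 20 fibrosis-up, 10 wound-healing-up), a mean-zero
per-(gene, day) shift shared by both conditions (SD 0.25 — day is nuisance
because the analysis pools days), and i.i.d. Gaussian log2 noise (SD 1);
values are exponentiated and multiplied by per-sample lognormal library
factors (CV 0.1). Noise is lognormal rather than count-based because the
pipeline consumes FPKM-like continuous values, not read counts; this
matches the variance-stabilized modeling surface. Companion generators
emit a GMT collection (one set padded with the planted fibrosis genes plus
size-matched random sets) and a long-format Ct fixture with
`Ct = a − log2(expression) + N(0, 0.1²)` whose fold changes follow the
planted effects.

What the generator does **not** emulate: count noise and
mean–variance coupling, correlated co-expression modules, batch effects,
annotation structure, and day-trending (rather than mean-zero) dynamics.
Passing tests therefore demonstrate the pipeline's statistical mechanics
and leakage hygiene, not performance on real transcriptomes.

## What small-n recovery can and cannot achieve

A deliberately documented negative result: with 4 + 4 training samples and
2000 genes, the univariate screen keeps ≈100 false positives — genes that
separate the training samples by chance, with training t-statistics (the
upper order statistics of ~2000 nulls) routinely exceeding those of
moderate planted effects (Δ = 3, i.e. E[t] ≈ 4.2). Measured over 20
simulated designs, even an oracle ranking of screened genes by training
|t| places only about half the planted genes in its top 10, roughly 15% of
planted genes fail the screen itself, and stability-selection recall of
planted genes is far lower still. This ceiling binds any selector that
sees only the training data; it is why the three tracks' panels mix
planted genes with screen false positives at moderate effect sizes, why
the tracks disagree with each other, and why holdout evaluation — not
selection frequency — is the arbiter of a panel's worth. At small scale
(hundreds of genes, a single 4σ effect) recovery is essentially certain,
and the test suite pins that regime down; the corresponding
study-design-scale recovery test records the measured recall/top-10/AUC
values in its assertion message.

## Defaults at a glance

| Stage | Parameter | Default |
|---|---|---|
| log transform | offset | 1 (TPM scale) |
| screen | δ, α, scales | 1 TPM, 0.05, diff on TPM / test on log2(TPM+1) |
| split | holdout per class, train | 5, 4+4 |
| LASSO | B, subsample, f*, grid, CV | 200, 75%, 0.5, 100 λ over 3 decades, 3-fold |
| SVM | C, γ, top-k, permutations | 1.0, scale, 5, 100 |
| RF | trees, features/split, examine, final | 500, 50%, 10, 3 |
| GSEA | weight p, permutations, set size | 1, 1000, 5–500 |
| ΔΔCt | reference, baseline, efficiency | GAPDH, WH, 2 |
| generator | genes, planted F/WH, Δ, σ, day SD, library CV | 2000, 20/10, 3, 1, 0.25, 0.1 |

All defaults are configurable through the corresponding `*Params`
dataclasses and the CLI.

## Known limitations

- Everything inherits the n = 18 design: per-gene holdout AUC has
  granularity 0.04, fold-level AUCs in the importance engine are coarse,
  and calibration with 8 training samples is sigmoid-only.
- The gene-set permutation null tests set membership, not phenotype
  association — standard practice at this n, but weaker than phenotype
  permutation.
- Stability-selection frequencies are solver-exact-zero based; a different
  L1 solver with soft zeros would need a support threshold.
- The pipeline assumes two conditions; the day label is carried and used
  for stratified reporting but never modeled.
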