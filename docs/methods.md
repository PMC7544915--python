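# Methods

This note documents the models, estimators and numerical choices behind
`rewirenet`, and what the synthetic test-bed does and does not establish.

## Data model and normalization

Counts are gene-level read counts, features × samples, one matrix per RNA
layer (PWBC mRNA, plasma miRNA). CPM uses the full library size — the
column sum over *all* features in the raw matrix, computed before biotype
subsetting or expression filtering — because recomputing library sizes
after subsetting would silently rescale every downstream unit. The fixed
pipeline order is: CPM on the raw matrix → expression filter (CPM ≥ 2 for
mRNA or ≥ 1 for miRNA, in ≥ 5 samples, thresholds inclusive) → biotype
subset. FPKM divides by transcript length (kb) and library size (millions).
All correlation work happens on log₂(CPM + 1); the pseudocount of 1 keeps
zeros finite and is conventional for this scale.

## Coexpression and rewiring

Pairwise Pearson correlations are computed by row standardization and a
single matrix product; features with zero variance (overall, or within a
group for the group-wise table) are excluded and logged. Nominal
significance for the all-sample network uses the Fisher z-transform normal
approximation, z = atanh(r)·√(n−3), with Benjamini–Hochberg FDR over all
pairs; |r| = 1 maps to the smallest positive double rather than 0. The
normal approximation is documented rather than any exact small-sample law:
at |r| > 0.98 every reasonable method is far beyond machine precision.

The rewiring rule compares a focal group's correlation r₁ with a
reference's r₂: inverted if |r₁ − r₂| > 1.95; gained (sign of r₁) if
|r₁| > 0.99 and −0.1 < r₂ < 0.1; lost symmetrically. All inequalities are
strict; under the default constants gained/lost and inverted regions are
disjoint (|r₁| > 0.99 with |r₂| < 0.1 gives a gap below 1.09). A
*consensus* edge receives the same non-NONE class against both reference
groups; pairs with two different non-NONE classes are flagged discordant
and reported separately, excluded from headline sets.

The rewiring eFDR permutes the outcome labels over all samples preserving
group sizes (6/6/5), recomputes group-wise correlations and the consensus
count per randomization, and reports mean scrambled count / observed count,
clipped to [0, 1]; zero observed yields 1 with a warning. Per-class eFDRs
(the same estimator restricted to each rewiring class) are reported
alongside the pooled value, since the class-wise and pooled nulls can
differ. With a seed the whole procedure is reproducible; 5000
randomizations is the reference default, reduced in tests for speed.

## miRNA:mRNA integration

Cross-layer correlations pair every miRNA with every gene over the same
animals. The all-sample selection keeps |r| > 0.85; its eFDR shuffles the
animal identities of the mRNA matrix only, which preserves both layers'
marginal and within-layer structure exactly while destroying the common
subject. Differential cross-layer coexpression reuses the rewiring rule
engine (0.99 / 0.1 constants by default; both thresholds are
configuration). Known interactions come from a user-supplied two-column
table; no database retrieval is performed.

## Consensus differential expression

Two in-house NB tests stand behind a pluggable contract (the role external
count-model engines play elsewhere; they can be swapped in, and pydeseq2 is
used as an independent cross-check in the test suite, never as the
implementation):

1. **Exact conditional test.** Counts are equalized to a common library
   (normalized by TMM or median-of-ratios effective libraries, rescaled to
   their geometric mean and rounded). Conditional on a gene's total
   pseudo-count t, the split into group A is tested two-sided by summing
   the probabilities of all splits no more likely than the observed one,
   with group sums NB(n·μ, φ/n); with φ = 0 this reduces to the
   binomial-conditional Poisson exact test. The implementation enumerates
   the full conditional support; an independent brute-force oracle checks
   it exhaustively at small totals.
2. **Wald test.** A log-link NB GLM fit by IRLS, vectorized across genes
   with fixed per-gene dispersion, offset log effective library; Wald p for
   the group coefficient, referred to a t distribution with residual
   degrees of freedom n − p (a small-sample correction for using estimated
   dispersions; with a known dispersion and the normal reference the test
   is calibrated, which the suite verifies). A cohort-year fixed effect can
   be added; the Wald test is the only test used when it is.

**Dispersion.** Raw per-gene estimates are pooled method-of-moments on
normalized counts, floored at zero. The mean–dispersion trend is estimated
per mean-quantile bin by maximizing the bin-pooled Cox–Reid adjusted
profile likelihood on the equalized pseudo-counts — the binned common
estimate is nearly unbiased where the per-gene moments estimator is noisy
and median-biased downward at n = 5–6. Genes are shrunk halfway to the
trend; the DE driver additionally floors each gene at its trend value,
because underestimated dispersions inflate both tests and the consensus
inherits the bias. Genes constant across all samples get φ = 0.

**Consensus, eFDR and the calibrated cut.** A gene is differential when
both tests give nominal p ≤ the cut-off. The cut-off itself is a
data-dependent choice calibrated against the empirical FDR: labels are
reshuffled across *all* samples of the design (all outcome groups, sizes
preserved), the contrast is recomputed on the samples carrying the
scrambled focal/reference labels, and the largest ladder value
(0.03, 0.01, 0.003, 0.001) whose consensus set has eFDR ≤ 0.05 is used.
Reshuffling over the full design rather than within the two contrast
groups matters at these sizes: a two-group-only shuffle reproduces or
reverses the true 6-vs-5 grouping often enough that genuinely differential
genes dominate the scrambled counts and the eFDR saturates regardless of
how clean the data are.

Two numerical details of the permutation arm: per-gene Wald dispersions are
re-estimated within each randomization (as when the analysis is rerun on
scrambled labels) and floored at the observed estimates, so a permutation
that happens to align with latent within-group structure is not awarded a
smaller dispersion than the data support; and the exact test's critical
split values, which depend on the selected samples' total pseudo-count, are
precomputed per gene on a grid of achievable totals (the observed total is
always a grid point) with each randomization's split projected onto the
nearest grid total. The projection is a deterministic, documented
approximation affecting only the permutation arm's boundary cases.

**Leave-one-out.** Each sample of the contrast is omitted in turn;
normalization factors are recomputed per round, dispersions held at the
full-data estimates; a gene is retained only if the consensus holds in
every round. Rounds that would leave a group below two samples are skipped
with a warning. Log₂ fold changes use normalized group means with
pseudocount 0.5; direction is their sign.

## Enrichment

Long transcripts attract more reads, so DE selection correlates with
length. The probability weighting function is fit by splitting the
background into 20 length-quantile bins, computing each bin's selected
fraction, and pooling isotonically (weighted by bin size) so weights never
decrease with length, floored at 10⁻⁶. The null draws |selected| genes
without replacement with probability proportional to the weights
(Gumbel-top-k sampling, vectorized); p_over = (1 + #{draws with in-term
count ≥ observed}) / (n + 1), so p is never zero. With flat weights the
null is exactly hypergeometric, which the suite verifies to Monte-Carlo
error. Terms are adjusted by Benjamini–Yekutieli (valid under arbitrary
dependency among overlapping terms); FDR < 0.10 is a reporting default,
not hard-coded. Term ancestry is not propagated; terms are flat sets.

## Outcome prediction

The feature panel is selected on both cohorts combined with year as a fixed
effect (BH FDR < 0.03 on the NB Wald p). Note the panel is selected before
the train/test split — faithfully reproducing the original design, in
which test-cohort samples contribute to feature selection; this is a known
information leak of that design and is flagged here rather than repaired.
The variance-stabilizing transform is log₂(normalized count + 0.5) with
per-gene centering and scaling by training-cohort parameters only
(zero-variance genes get scale 1, flagged); the exact transform of the
reference count-model package is not reproduced and this stand-in is the
documented contract. The classifier registry covers five families (random
forest, LDA, L2 logistic regression, RBF SVM, k-NN) screened by stratified
cross-validated training accuracy with a 0.9 flag threshold; the seed sweep
refits the chosen algorithm (default: 500-tree random forest, √p features
per split) with seed base_seed + i, reporting per-run accuracy, the
histogram of correctly classified test animals, and mean impurity-based
importance with ranks. Accuracy p-values are exact binomial against the
majority-class (no-information) rate.

## Synthetic data

Counts are gamma–Poisson: y ~ Poisson(Gamma(1/φ, φλ)), λ = exp(baseline +
group effect + year effect + latent signal), giving NB mean–variance
m + φm². Baselines are log-normal (median 1200 counts, log-sd 1);
dispersion defaults to 0.2; the default design is 17 animals in groups of
6/6/5, optionally two cohort years with per-gene year shifts (log-sd 0.2);
planted-edge features are exempt from year shifts and their signals are
constructed over the pooled outcome groups, so the planted class remains
well-defined on the pooled within-group correlation the pipeline measures.

Planted correlations are constructed on the *realized* sample scale: the
focal group's two latent vectors are built with empirical correlation
exactly equal to the target (Gram–Schmidt construction), and reference
groups' vectors are built empirically orthogonal. This is deliberate: with
5–6 samples the sample correlation of independent vectors has SD ≈ 0.45,
so population-level planting can essentially never satisfy the strict
−0.1 < r < 0.1 absence band, and recovery statements would be vacuous.
Count noise attenuates a planted correlation by roughly s²/(s² + φ + 1/μ)
for latent signal variance s²; in addition, CPM injects a common-mode
library-size term into every pair, which attenuates negative correlations
preferentially. Planted-edge features therefore default to moderate
abundance (μ = 1000), tight dispersion (5·10⁻⁴) and amplitude s = 1.2, and
must stay a small share of the library — fixtures keep the planted share
below ~10%. The expected attenuation is recorded in the truth tables.
Planted DE genes default to dispersion 0.05 with log₂ fold change 2.6 in
the default two-cohort fixture — effects strong enough to survive
leave-one-out at n = 5–6 but near enough to the detection limit that
partially aligned label permutations do not re-detect them.

What passing tests show — and don't. The generator produces clean NB noise
with exactly planted structure; real data add outliers, batch effects,
compositional artifacts, correlated nulls and library-size pathologies that
the fixtures do not emulate. Recovery and calibration results on fixtures
establish the estimators' correctness under their stated model, not field
performance. Two honest properties of the eFDR estimator surface even on
fixtures: permutations that nearly reproduce the true grouping re-detect
genuine effects (an irreducible floor on the eFDR when effects are strong
and groups small), and genes with large latent within-group variability
enter the scrambled counts at an elevated rate.

## Problem sizes

The test suite and the acceptance script run reduced but statistically
meaningful sizes chosen as the package's defaults for a desk-scale
validation: 300–2000 genes, 50 planted edges, 120 planted DE genes,
300–500 permutations, 200 prediction seeds. The reference defaults for a
real analysis (5000/10000 permutations, 2000 prediction seeds, full gene
complements) are the configuration defaults of the pipeline module.
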