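# rewirenet

Multi-layer transcriptome analysis of pregnancy outcome in beef heifers —
and, more generally, of any small-cohort bulk RNA-seq design with two or
three outcome groups and two molecular layers profiled from the same
subjects.

Blood drawn at the time of artificial insemination (AI) yields two count
matrices per animal: protein-coding gene counts from peripheral white blood
cells (PWBCs) and circulating miRNA counts from plasma. Animals are later
classified as AI-pregnant, pregnant to natural breeding (NB-pregnant) or
non-pregnant. `rewirenet` implements the statistical machinery that turns
those matrices into biology:

- **Coexpression network** — pairwise Pearson *r* on log₂(CPM + 1) across
  all animals; Fisher-z p-values, Benjamini–Hochberg FDR, edges kept at
  |r| > 0.98 and FDR < 0.02.
- **Differential coexpression (rewiring)** — within-group correlations
  compared between the non-pregnant (focal) group and each pregnant group:
  an edge is *inverted* when |r₁ − r₂| > 1.95, *gained/lost* when
  |r₁| > 0.99 while −0.1 < r₂ < 0.1 (all strict). A consensus edge receives
  the same class against both references. Significance is an empirical FDR
  (eFDR): outcome labels are permuted (group sizes preserved), the
  consensus count recomputed, and eFDR = mean scrambled count / observed
  count.
- **miRNA:mRNA integration** — cross-layer correlations at |r| > 0.85 with
  an identity-shuffle eFDR (the mRNA matrix's animal identities are
  permuted, breaking the common source of the two RNA layers), the same
  rewiring rules across layers, and an overlay of known miRNA–target
  interactions.
- **Consensus differential expression** — a gene is differential only if a
  conditional NB exact test *and* an NB Wald test (IRLS log-linear model,
  optional cohort-year fixed effect) both give nominal p below a cut-off
  calibrated so that the permutation eFDR is ≤ 0.05; calls must then
  survive leave-one-out revalidation in every round.
- **Length-aware enrichment** — a probability weighting function (selection
  probability as an isotonic function of transcript length) feeds a
  weighted resampling null; terms are adjusted with Benjamini–Yekutieli and
  reported at FDR < 0.10.
- **Cross-year outcome prediction** — a year-adjusted DE panel
  (FDR < 0.03), variance-stabilized expression, a registry of classifier
  families screened by cross-validation, and a repeated-seed random-forest
  sweep that blind-predicts the second cohort; outputs the distribution of
  correctly classified animals over seeds and per-gene variable importance.
- **Synthetic data** — a negative-binomial (gamma–Poisson) generator that
  plants rewired edges, cross-layer couplings, DE genes and year effects
  with truth tables, so every stage is testable without any download.

## Worked example

```python
from rewirenet import (log2_cpm, groupwise_correlation,
                       consensus_rewired_edges, efdr_rewiring)
from rewirenet.simulate import planted_rewiring_spec, simulate_dataset

ds = simulate_dataset(planted_rewiring_spec(n_edges=25, n_genes=300, seed=2))
em = log2_cpm(ds.mrna)
edges = consensus_rewired_edges(groupwise_correlation(em, ds.samples))
print(edges[~edges.discordant].rewire_class.value_counts())
ef = efdr_rewiring(em, ds.samples, n_randomizations=200, seed=7)
print(f"eFDR = {ef.efdr:.4f} ({ef.observed} observed, "
      f"{ef.mean_scrambled:.2f} scrambled)")
```

prints

```
rewire_class
GAINED_POSITIVE    15
GAINED_NEGATIVE    13
Name: count, dtype: int64
eFDR = 0.0450 (28 observed, 1.26 scrambled)
```

Twenty-five gene pairs were planted to be tightly correlated only in
non-pregnant animals; the consensus rule recovers them (the three extra
edges are sampling noise), and permuting the outcome labels produces on
average 1.26 such edges against 28 observed — an empirical FDR under 5%,
i.e. the detected rewiring is group-specific, not chance.

The `examples/` directory walks through every capability (filtering,
network, rewiring, integration, DE, enrichment, prediction), each printing
its numbers with a line on what they mean. A thin CLI covers fixture
generation and orchestration: `rewirenet simulate --out dir/` and
`rewirenet run --config cfg.yaml`.

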