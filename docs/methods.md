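# Methods

## Scope and data model

`phenodeep` classifies host phenotype from taxonomic abundance profiles.
The canonical in-memory object is a dense samples × taxa matrix
(`AbundanceTable`) whose taxa carry full lineages in the pipe-joined,
rank-prefixed convention (`k__...|p__...|...|s__...`), plus a sample →
label mapping (`SampleMetadata`) whose label encoding is frozen at
construction: labels are sorted lexicographically and indexed 0..N−1, so
the integer codes never depend on which subset of samples is in view.

Three input dialects are read: generic TSV OTU tables (taxa rows × sample
columns), per-sample Kraken2-style reports, and MetaPhlAn-style merged
percent tables. Kraken lineages are reconstructed from the report's
2-space indentation; only the primary rank codes D/K/P/C/O/F/G/S become
features (D and K both map to the kingdom slot), while root, unclassified
and suffixed sub-rank rows (S1, G2, …) stay on the indentation stack but
are never selected at any rank. Which report column is used (clade read
count vs. percent) is a reader flag; the default is the clade count, since
count tables can always be closed to percentages downstream. After any
multi-file merge the taxon order is canonicalised lexicographically by
display id so the model's feature order is reproducible. Taxa missing from
a sample are zeros, not missing values.

A generic-TSV table's value kind is inferred: if every sample's
species-rank values sum into [99, 101] it is treated as percent, otherwise
as counts; ambiguous tables can be forced with an explicit argument.

## Preprocessing

Fixed order: rank restriction → closure to relative percent → abundance
filter → CSS normalisation (optional) → split / feature assembly.

* **Abundance filter.** A taxon is retained when its *maximum* relative
  abundance over the reference samples is ≥ the threshold, boundary
  inclusive. The threshold (default 0.03) is on the percent scale: 0.03 %
  keeps rare-but-present markers, whereas a 3 % floor would strip almost
  every species-level taxon from a typical profile. When a split is in
  effect the reference set is the training partition only, and the
  retained list is stored in the model archive, so the test partition and
  future unknown samples never influence feature selection.
* **CSS.** Per sample the scaling factor is the sum of values up to the
  sample's q-th positive-value quantile (linear-interpolation quantile,
  q = 0.5 by default and exposed); the reference scale is the median
  factor of the *training* samples. At prediction time factors are
  computed fresh per sample and the stored reference is reused, which
  makes a sample's normalised row independent of whichever samples
  accompany it. The adaptive per-dataset quantile selection of the
  original CSS formulation is deliberately out of scope.
* **Split.** Per class: seeded shuffle, then `round(test_fraction · n_c)`
  (half-away-from-zero, minimum 1) test samples, the same rule for
  validation on the remainder. Per-class deviation from exact proportion
  is below one sample.

Replaying the stored retained-taxa list and CSS state on the training
table reproduces the training feature matrix bit-for-bit; the test suite
asserts this.

## The classifier

`n_layers` hidden linear layers (the output layer is additional) of
`n_neurons` each; every hidden layer is followed by an ELU activation and,
when enabled, an inverted-dropout layer; a final linear layer produces one
logit per class. Softmax is applied only at prediction time — the training
loss is cross-entropy on raw logits through a fused log-softmax, avoiding
a double softmax. Optimisation is Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) with L2
weight decay folded into the gradient, mini-batches of `batch_size` with
per-epoch reshuffling from a seeded generator; the last batch may be
smaller. Defaults: 10 layers, 25 neurons, dropout on at 0.5, learning rate
3e-5, weight decay 0, batch 50, 20 epochs. The epoch with the highest
validation accuracy supplies the returned weights (ties → earliest); with
no validation set, the final epoch's. A non-finite loss aborts training
with a "diverged" error naming the epoch.

Everything is numpy: forward, backward and the optimiser are implemented
directly, which keeps the package dependency-light and every number
reproducible from the seed alone. Initialisation is He-normal for hidden
weights, zero biases, and an all-zero output layer, so an untrained
network predicts exactly the uniform distribution and early training
signal is not masked by random output weights. There is no batch
normalisation and no learning-rate schedule.

The model archive is a zip with JSON members (network and preprocessing
config, label order, CSS state), a plain-text retained-taxa list, an NPZ
weight blob, and a `format_version` member ("1"). Loading reproduces
predictions bit-for-bit; truncated or alien files raise a descriptive
archive error.

## Randomized search

Configurations are drawn independently: layers and neurons uniform
inclusive on [5, 75], dropout enabled by a fair coin (rate uniform on
[0.1, 0.9] only when enabled), weight decay uniform on [0, 0.1], and the
learning rate log-uniform on [5e-6, 5e-4] — it spans two orders of
magnitude, so uniform sampling would all but ignore the lower decade.
Trial *i* trains with seed `search_seed + i` on one fixed split (the
search does not re-split per iteration). The stopping rule counts
consecutive trials without a *strict* improvement of the best validation
accuracy and stops at `patience` (default 10); a diverging trial scores 0
and the search continues, erroring only if every trial diverged.

## Metrics

Binary precision/recall/F1 take label index 1 (the lexicographically
second label) as the positive class unless overridden; zero denominators
yield 0 by convention. Multiclass metrics are macro one-vs-rest. The ROC
sweeps distinct scores descending with ties grouped and the AUC is the
trapezoid rule — the suite checks it against the pairwise Mann–Whitney
statistic to 1e-9. A single-class truth leaves the AUC undefined rather
than raising. Cross-validation is stratified k-fold (default k = 5) with
the abundance filter and CSS reference refit inside each fold on its
training portion.

## The synthetic cohort generator

Per sample, latent per-taxon abundances are log-normal(μ, σ); in case
classes a fixed block of informative taxa is multiplied by
exp(log-fold-change); independent zeroing at the sparsity rate emulates
zero inflation; the composition is closed and scaled to integer counts at
the configured depth. Defaults describe the benchmark cohort used
throughout the tests: 2 × 100 samples, 200 species, 20 informative,
log-fold-change 3, σ = 1, 30 % sparsity, depth 10⁵ — sizes at which every
check runs in seconds on one core. Species are grouped ten to a genus so
the Kraken renderer has a non-trivial hierarchy whose internal clade
counts are sums of their children.

What the generator does *not* emulate: taxon–taxon correlation and
ecological interactions, phylogenetic signal, batch effects, and
compositional bias between cohorts. Passing tests therefore demonstrate
the pipeline's mechanics and its ability to recover independent
multiplicative effects — not performance on real cohorts, where effects
are weaker and correlated.

## Numerical and design notes

* ELU is computed via `expm1` on the negative branch only, avoiding
  overflow warnings on large positive inputs.
* Argmax ties in prediction break toward the lowest class index.
* Probability rows sum to 1 within 1e-6 (softmax of shifted logits).
* `n_layers` counts hidden layers because the tuning range 5–75 only makes
  sense for hidden depth.
* At the default learning rate and epoch budget, small cohorts receive
  very few optimiser steps (a 200-sample cohort yields ~80 Adam updates),
  which is enough to learn the class *ranking* (high AUC) but not to
  calibrate the decision threshold: accuracy can sit at chance while AUC
  is near 1, with the confusion matrix collapsed onto one predicted
  class. More samples, more epochs, or a larger learning rate (the tuning
  range reaches 5e-4) resolve this; the acceptance script reports default,
  converged and tuned configurations side by side so the distinction is
  visible.
* Known limitations: no GPU path, no rarefaction/TSS/TMM/CLR alternatives,
  no phylogeny-aware features, no BIOM or QIIME2 artifact input.
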