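# Methods

## Problem and model

The task is multi-label prediction of phenotype-term annotations for genes.
The working hypothesis is that functionally related genes — genes that
interact and share functional (GO) annotations — tend to produce similar
phenotypes. The pipeline therefore learns gene representations from an
attributed interaction network before any phenotype label is consulted, and
only uses labels in a final supervised classifier. This matters because the
annotated-gene set is small: representations trained transductively on the
full network also cover genes with no annotation history, which is exactly
the population temporal validation probes.

### Dataset construction

Annotations are propagated by the true-path-rule (a gene annotated to a term
is implicitly annotated to every `is_a` ancestor), optionally restricted to a
single ontology branch, and terms annotating ≤ 10 genes are removed.
Surviving terms are binned by annotated-gene count (11–30, 31–100, 101–300,
> 300) so evaluation can expose performance on rarely annotated terms.
Counting is single-pass: removing sparse terms can orphan genes and thereby
lower other terms' counts, but counts are not recomputed after removal —
the filter is a one-shot partial-evaluation rule, not a fixpoint. The branch
root itself is excluded from the label space by default because after
propagation it annotates every retained gene and carries no signal.

### Attributed network

Edges come from a scored interaction list thresholded at 0.3 (raw STRING
0–1000 integers are rescaled by 1/1000 behind a reader flag; the core
builder accepts only scores in [0, 1]). Duplicate pairs take the max score;
self-edges are dropped. Genes present in the annotation tables but absent
from the interaction file are kept as isolated nodes — the filter's implicit
self-loop still propagates their own attributes. Binary GO indicator
attributes are compressed by PCA (default 1000 components at real-data
scale); the projection is fit on all genes (transductive), with each
component's sign fixed so its largest-magnitude loading is positive, making
results reproducible across runs.

### Laplacian smoothing

With `Ã = I + A`, `D̃` its degree matrix, `L̃ = D̃ − Ã`, and
`L̃_sym = D̃^{-1/2} L̃ D̃^{-1/2}`, the filter is `H = I − αL̃_sym`. Since
`L̃_sym` has spectrum in [0, 2), α = 2/3 keeps every eigenvalue of H inside
[−1/3, 1]: high graph frequencies (neighbour-inconsistent components) are
damped hardest, the graph-constant component is preserved exactly. Features
are smoothed as `X̃ = HᵗX`, default t = 2, computed as t sparse
multiplications (never a materialized dense power). A `laplacian_sign`
switch ("minus"/"plus") exists because the additive form `D̃ + Ã` circulates
in some descriptions of this filter family; it is not a Laplacian and
anti-smooths, so "minus" is the default and "plus" exists only for
replication experiments.

### Self-supervised pretraining

The encoder is deliberately linear, `Z = X̃W` with per-column min-max
scaling to [0, 1] (a constant column scales to zeros). Scaling keeps Z
non-negative so every pairwise cosine similarity lies in [0, 1] and can be
read directly as a Bernoulli probability in the pretext loss — this internal
consistency is why scaling is recomputed at every forward pass rather than
once. The pretext task ranks all unordered gene pairs by similarity
(descending, ties broken lexicographically by index pair for determinism),
takes the top k as positives and bottom k as negatives, and minimizes the
summed binary cross-entropy of the pair similarities against those labels
with Adam (lr 0.001). Pairs are re-selected every epoch by default
(`reselect_every`). Defaults: embedding width 2048 at real-data scale,
k = 10·n when unset. Gradients flow through the cosine similarity and the
linear map; the per-column min/max of the scaling step are treated as
stop-gradient constants. This keeps the backward pass smooth (the
subgradient contribution of the single argmin/argmax entries is measure-zero
noise) and is recomputed exactly at the next forward pass. The dense n×n
similarity matrix is only materialized below a configurable ceiling (20 000
genes); larger problems are refused with a pointer to batched ranking rather
than silently thrashing.

Training dynamics worth knowing: the within-cluster/between-cluster
similarity gap widens over the first tens of epochs and can shrink again
with very long training, because once the easy pairs saturate, the top-k
window starts admitting cross-cluster pairs and pulls them together too.
The default epoch budget (60 on the benchmark) sits in the widening regime.

### Classifier

A feed-forward network with three hidden layers (affine → batch
normalization → LeakyReLU slope 0.01) and a sigmoid output unit per term,
trained with Adam (lr 0.001, batch 128) on the mean binary cross-entropy
over gene–term cells (the summed and mean losses differ by a constant
factor only; the mean keeps the learning rate problem-size independent).
Batch-norm running statistics (momentum 0.1) make inference
batch-independent to numerical precision. Hidden widths are not dictated by
the method, only the layer count; defaults are 1024/512/512 at real-data
scale. Epochs default to 200 with patience-20 early stopping on a 10%
validation split of the training genes; the best-validation parameters are
restored. The classifier satisfies a minimal scorer protocol
(`fit`/`predict_proba`), so classical baselines (SVM, random forest,
logistic regression) can be slotted in for comparison without being
reimplemented here. Everything — encoder, backprop, batch-norm, Adam — is
implemented in NumPy.

### Evaluation

Term AUPR is stepwise average precision over distinct score thresholds (tied
scores form one block); trapezoidal interpolation is deliberately avoided as
optimistic for PR curves. Fmax is the maximum F1 over the grid
τ ∈ {0.00, 0.01, …, 1.00}. Macro variants average per-term metrics over
terms with ≥ 1 positive test label; terms without test positives are
excluded from macro averages and from the micro flattening within their
scope, so undefined precision/recall never pollutes an average (an absent
value is reported as an explicit sentinel, never as 0). Macro-Fmax defaults
to the mean of per-term maxima (each term at its own best threshold); a
shared-threshold variant (one τ maximizing the mean F1) is available behind
`eval.shared_threshold_fmax`. Cross-validation shuffles genes with a seed
and deals them round-robin into 5 folds; out-of-fold predictions are pooled
into one gene×term matrix evaluated once, which stabilizes AUPR for rare
terms relative to averaging per-fold estimates. The temporal split takes as
test genes exactly those with zero earlier-snapshot annotations and ≥ 1
later-snapshot annotation.

## Synthetic benchmark

The generator is a stochastic block model with co-dependent attributes and
labels — the minimal model in which topology, attributes, and phenotypes
all reflect the same latent functional grouping. Defaults: n = 300 genes in
B = 3 blocks, edge probabilities p_in = 0.2 / p_out = 0.02, 60 binary
attributes each tied to one block (active with probability 0.3 in its
block, 0.05 elsewhere), 20 phenotype terms each linked to one or two blocks
(annotation probability 0.6 in linked blocks, 0.05 elsewhere), 2% label
noise, seed 17. The sparse attribute probabilities emulate real GO
indicator vectors: individual columns are weakly informative and the
aggregate is noisy, which is the regime where dimensionality reduction and
graph smoothing earn their keep. Snapshot mode hides all annotations of a
seeded 10% of annotated genes at t0.

What the benchmark does *not* emulate: real degree and annotation-count
distributions are heavy-tailed, ontology depth is much larger, and label
sparsity per term is far more extreme. Passing results here show the
pipeline recovers planted co-dependence structure and that every stage
composes correctly; they do not certify real-data performance levels.

The benchmark runs with a scaled configuration (`benchmark_config`): 50 PCA
components, 128-dim embeddings, 60 pretraining epochs, 256/128/128 hidden
layers, 100 classifier epochs with patience 10. These are the package's own
problem-size choices for a 300 × 60 instance; the real-data defaults above
remain the config defaults.

## Numerical choices and degenerate inputs

* Pair similarities are clamped to [1e-15, 1 − 1e-15] inside the pretext
  loss, so saturated pairs contribute a large finite penalty.
* All-zero embedding rows get similarity 0 to everything (logged); they are
  excluded from the gradient.
* PCA output width is truncated to the numerical rank of the centered
  matrix when the requested dimension exceeds it (warned, not an error).
* A constant encoder column min-max scales to zeros by convention.
* Fold assignment, pair ranking, and tie-breaks are all deterministic given
  the global seed, which fans out to per-stage seeds by fixed offsets
  (pca +1, ssl +2, classifier +3, cv +4).
* Artifacts embed the SHA-256 fingerprint of the producing config; a rerun
  with a different config refuses to overwrite mismatched artifacts.

## Known limitations

* The dense pairwise-similarity matrix bounds the pretraining to ~20k genes
  as shipped; batched top-k/bottom-k ranking would be needed beyond that.
* No hierarchical consistency post-processing of predictions over the
  ontology and no probability calibration.
* Gene identifier mapping (gene symbol ↔ protein accession) is the caller's
  responsibility; inputs must arrive in one namespace.
* The min-max stop-gradient is an approximation to the exact subgradient of
  the scaled encoder; in practice the loss traces are monotone to within a
  few upticks per hundred epochs.
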