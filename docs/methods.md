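# Methods

## Data model and preprocessing

The package ingests gene-level (or probe-level) intensity tables with a
two-class phenotype label per sample.  The fixed preprocessing order is

1. **probe collapse** — probes mapping to one gene are combined by the
   arithmetic mean (a max rule is available behind a flag); the mean is
   the least-surprising symmetric choice when nothing is known about
   probe quality;
2. **log2 with cutoff** — `log2(max(v, 1))`, so the output is
   non-negative and roughly normal for intensity-scale data (skipped
   when the input is already on a log scale);
3. **per-sample standardization** — each sample row is centered and
   scaled to population (1/N) variance 1 across its measured genes.
   Standardizing per sample (not per gene) removes per-array intensity
   offsets; the 1/N vs 1/(N−1) choice is immaterial at thousands of
   genes but is fixed and stated.  Rows that are constant up to
   floating-point rounding cannot be standardized and raise;
4. **alignment to the pathway universe** — the gene order becomes the
   union of all gene-set members in first-appearance order; pathway
   genes absent from the data are filled with exact zeros, measured
   genes outside every pathway are dropped.  Alignment runs *after*
   standardization so injected zeros stay exactly zero.

Standardization happens over all measured genes, then alignment; doing
it the other way would let the injected zeros shift the per-sample
moments.

## Pathway graphs

Each gene set becomes an undirected 0/1 graph over its member genes;
node identity is (pathway, gene), so a gene in several pathways yields
distinct nodes.  Edges come from a flat TSV (`pathway, gene_a, gene_b`);
rows with unknown pathways, non-member genes, or self-loops are dropped
with a counted warning, and a pathway without edge rows is simply
edgeless — isolated genes are retained because pooling averages over
all member nodes.  The convolution operator is the renormalized
adjacency `S = D̃^{-1/2}(A+I)D̃^{-1/2}`: adding the self-loop before
degree normalization keeps every node's own signal and bounds the
spectrum, and for a d-regular graph reduces to `(A+I)/(d+1)`.

## Classifier

The GCN applies two graph convolutions with weights shared across all K
graphs, so the trainable parameter count grows with K only through the
head (K·10·2 + 2 head parameters).  Layer order is conv → ReLU →
batch-norm → dropout for the first convolution and conv → ReLU for the
second, which feeds the per-graph average pooling directly; the
activation after each convolution follows the propagation rule, while
the placement of batch-norm before dropout within a block is a fixed
convention of this implementation (the alternatives are not
distinguishable from first principles).  Convolutions carry no additive
bias; batch-norm supplies the affine shift.  All K graphs are assembled
once into a block-diagonal sparse operator; a minibatch is processed as
one `(samples, Σ N_k)` gather followed by sparse propagation, and this
is numerically identical to looping over graphs one at a time (asserted
in the tests).

Training: Adam on class-weighted cross-entropy (weights are inverse
class frequencies normalized to mean 1) plus an L2 penalty on the
weight matrices (batch-norm parameters and biases excluded).  Early
stopping monitors the epoch-end full-data loss in evaluation mode —
the validation loss when a validation split is supplied (as inside CV
folds), the training loss otherwise — and stops after `patience = 5`
consecutive epochs without a new minimum, restoring the best state.
One integer seed drives initialization, shuffling and dropout; two fits
with the same seed produce bit-identical weights.

The MLP baseline (three fully connected layers on the raw gene vector)
and the GCN-MLP (the same conv trunk with a three-layer head) share the
training engine; hidden linear blocks use linear → ReLU → batch-norm →
dropout.

The decision cutoff is chosen on training scores by maximizing Youden's
J over the observed score values (rule `score ≥ t`), breaking ties
toward the candidate nearest 0.5.  Reported metrics are standard
one-vs-rest binary accuracy/precision/recall/F1 with a configurable
positive class; undefined ratios are reported as 0 and flagged.  (For
binary classification, micro-averaged precision and recall both equal
accuracy, so asymmetric precision/recall figures can only arise from
the one-vs-rest convention — which is therefore the one implemented.)

Hyperparameters are selected by random search over user-supplied value
lists, scored by stratified five-fold CV mean validation accuracy, ties
broken by mean F1 and then by fewer trainable parameters.

## Shapley attribution

The explained quantity is the pre-softmax logit margin (positive minus
negative class), not the probability.  This choice makes the GCN head
*exactly linear* in the pooled features, so pooling-layer Shapley
values have the closed form `φ_i = w_i (z_i − E_bg[z_i])` — exact for
every coalition ordering, with local accuracy `Σφ + base = margin`
holding to machine precision.  The background is the explained samples'
own pooled activations by default (subsampled above 1,000 samples).
For the nonlinear GCN-MLP head, a permutation-sampling estimator is
used; its per-permutation contributions telescope, so local accuracy is
exact for the sampled estimate too, and the values converge to the
coalition enumeration as permutations grow.  Pathway importance is the
mean |φ| over a pathway's 10 pooled channels and all samples; only
absolute values enter the ranking because different channels of one
pathway may push toward different classes.

Gene-level attribution uses expected gradients — integrated gradients
(midpoint rule, 25 steps by default) averaged over up to 25 background
references — which satisfies completeness in the limit and in practice
reconstructs the margin to within a few percent; constant features
(e.g. zero-filled unmeasured genes) receive exactly zero.

## GSEA comparator

Genes are ranked by the signal-to-noise ratio
`(mean_0 − mean_1)/(sd_0 + sd_1)` with each class SD floored at
0.2·|class mean| (the GSEA software convention); ties keep input order.
The enrichment score is the signed maximum deviation of the weighted-KS
running sum (hit steps `|s|^p / Σ_hits |s|^p` with p = 1 by default,
miss steps `1/(N − |S|)`); when several positions tie in |deviation|,
the earliest wins.  Null distributions come from phenotype permutation
(label permutation preserves class counts, so both classes always stay
populated): NES divides ES by the mean |null ES| of matching sign,
the nominal p-value is the fraction of same-sign null ES at least as
extreme, and FDR q is the GSEA tail ratio of null-vs-observed NES
fractions, clipped to [0, 1].  An ES of exactly 0 (possible only in
degenerate inputs) is assigned NES 0 and p 1 by convention.  Weighted
p = 1 and signal-to-noise ranking are the defaults because they are the
GSEA software defaults; both are configurable.

## Rank-window validation

Windows are consecutive, disjoint blocks of the importance ranking —
5 pathways (gene union, deduplicated within a window) or 100 genes by
default.  Each window independently trains an L2 logistic regression
(class-balanced weights, inverse regularization strength fixed at 1.0
across windows so only the feature set varies) on the training split
and is scored on the test split; the summary is the OLS slope of F1
against window index.  A duplicated feature under the ridge penalty
splits its coefficient mass equally and behaves like a single copy at
half the penalty, which is why window contents are deduplicated.

## Synthetic study

The generator emulates a two-subtype expression study: 40 pathways of
25–35 genes (roughly the low end of KEGG pathway sizes), 10% of each
pathway's genes shared with its neighbor, Erdős–Rényi within-pathway
edges at density 0.15 (the empirical mean density of the KEGG pathway
graphs), 100 samples per class in independent train and test draws,
values on a log2-intensity-like scale (baseline mean 7, SD 1).  Four
pathways carry signal:

* **mean shift** (2 pathways): member genes move ±δ/2 per class with
  δ = 1 noise-SD — a standard, per-gene-detectable effect size;
* **correlation flip** (2 pathways): member genes load on a shared
  latent factor with loading magnitude √0.8 and signs that are uniform
  in class 0 but alternate in class 1.  Per-gene marginals are
  identical across classes by construction; only the gene–gene
  correlation (±0.8) distinguishes the classes.  The GCN can detect
  this because neighbor aggregation followed by ReLU converts the
  class-dependent variance of pathway-local sums into a class-dependent
  pooled mean.

Informative pathways are spaced three apart so their member genes never
overlap each other.  What the fixture does *not* emulate: probe-level
artifacts, batch effects, heavy-tailed intensity noise, pathway-size
skew, and correlated background between pathways.  Passing the
recovery tests therefore shows the method's mechanics work under clean
planted signal, not that it overcomes real-data confounders.

## Problem sizes and numerical choices

Shipped tests and the acceptance script run the default study
(40 pathways, ~1,100 genes, 200 + 200 samples), a 186-pathway
architecture check at reduced pathway size, GSEA with 1,000 phenotype
permutations (500 for the null calibration over 50 disjoint sets), and
brute-force oracles at N ≤ 10–30 — sizes chosen so the full analysis
completes in a few minutes on one CPU while leaving every statistical
conclusion comfortably outside its noise band.  Tolerances: exact
closed forms are checked at 1e-8–1e-12; the stochastic gene-level
attribution at 5% of the mean |margin|; the GSEA null calibration at
three binomial standard errors around 5%.

## Known limitations

* Binary phenotypes only; no multi-class or survival outcomes.
* Edges are untyped and unweighted; activation/inhibition annotations
  are ignored by design.
* The permutation-sampling Shapley estimator for nonlinear heads is
  O(features × permutations × background) and is meant for pooled
  features (K·10), not for gene-level use.
* GSEA omits leading-edge extraction and gene-tag permutation.
* The NumPy training loop is single-threaded apart from BLAS; it is
  sized for thousands of genes and hundreds of samples, not for
  atlas-scale single-cell matrices.
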