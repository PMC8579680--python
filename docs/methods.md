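# Methods

## Problem setting

Expression studies in the small-sample regime (tens of samples, hundreds to
tens of thousands of genes) need gene selectors whose output can be trusted
twice over: the selected panel should classify well, and it should not
change wholesale when the training examples are perturbed slightly. Plain
SVM-RFE — recursively train a linear SVM, drop the genes with the smallest
squared weights — is accurate but notoriously unstable in this regime: a
single relabelled or resampled example can reorder the tail of the weight
vector and cascade through the elimination schedule.

`rsgsa` implements a two-stage selector built around that failure mode,
together with the evaluation protocols used to quantify it and a synthetic
generator that plants known signal for testing.

## Stage 1: correlation-graph pruning

Highly correlated genes carry near-duplicate information; they slow the
ranking stage and dilute weight mass across near-copies. Stage 1 removes
them with a graph procedure rather than greedy pair deletion:

1. Build an undirected graph with one node per gene and an edge wherever
   the Pearson correlation r of the two expression profiles satisfies
   r ≥ λ (default λ = 0.9). A signed threshold is the method as stated; an
   `absolute` mode (|r| ≥ λ) is available behind a flag because strongly
   anti-correlated genes are equally redundant.
2. While any edge remains: compute eigenvector centrality within each
   connected component, take the globally highest-scoring node as a
   *leader*, record its current neighbours as its *members*, and delete
   leader and members from the graph. Centrality is recomputed from
   scratch after every deletion.
3. When the graph is edge-free, every surviving isolated node becomes a
   leader with no members.

Leaders form an independent set of the original graph and, with their
members, partition the gene set; members are carried through to the final
report as satellite annotations of their leader, so no gene identifier is
lost. Only leaders are ranked and only leaders count toward top-X
selections.

**Numerical choices.** Eigenvector centrality of a component is the
principal eigenvector of its 0/1 adjacency, max-normalised so the top score
is 1. It is computed by power iteration from an all-ones start with
max-norm scaling (tolerance 1e-12, cap 100,000 iterations). The iteration
runs on A + I rather than A: the shift leaves all eigenvectors unchanged
but makes the matrix primitive, so the iteration also converges on
bipartite components, where plain power iteration oscillates with period 2.
Ties in the maximum score (within 1e-12) break toward the lowest gene
index, making extraction fully deterministic. Constant-expression genes are
defined to have correlation 0 with everything — they carry no
co-variation signal, are never pruned as redundant, and are eliminated
early by the ranking stage instead.

## Stage 2: stable SVM-RFE with bootstrap aggregation

One run of the stabilised recursion (SSVM-RFE) proceeds in steps. At step
r, with n surviving genes:

1. Train an ensemble of |L| linear SVMs (default 10) on per-gene z-scored
   values. Each member sees the same expression matrix but with a fraction
   f (default 0.03) of class labels flipped uniformly at random to a
   different class.
2. Normalise each member's weight vector to unit 1-norm,
   w′ = w / Σᵢ|wᵢ|, so members contribute on a common scale.
3. Aggregate per-gene importance as the ensemble sum of squares,
   Wᵣⁱ = Σₗ (w′ₗⁱ)².
4. Drop the max(1, ⌈0.10 · n⌉) genes with the lowest Wᵣ (never dropping
   below the target count, default 50). The geometric schedule keeps the
   number of recursive steps logarithmic while still producing
   fine-grained ranks.

Survivors receive ranks 0..k−1 by descending final importance; eliminated
genes follow in reverse elimination order (within one step, by descending
importance at elimination time). Importance ties break toward the lower
gene index. The result is a full permutation of the leader genes.

Robustness to sample perturbation comes from wrapping the recursion in m
full-size bootstrap resamples (default m = 10, matching the 10-repetition
evaluation protocol; the bootstrap fraction is configurable). Run i yields
integer ranks sᵢʲ; the final order ascends in the rank sums sʲ = Σᵢ sᵢʲ.
Rank-sum ties break by the mean aggregated importance at the first
recursive step — the only step at which every gene is present in every
run — then by gene index.

If the classes are imbalanced, the dataset is balanced once, before
pruning and bootstrapping, by synthetic minority oversampling: each new
sample is x + u·(x_nn − x) for a minority sample x, one of its k = 5
nearest minority neighbours (k capped at minority size − 1) and
u ~ U[0, 1]. A singleton minority class cannot be interpolated and falls
back to jittered duplication (Gaussian noise at 1% of the per-gene SD)
with a warning.

**SVM details.** The linear SVM is the soft-margin hinge-loss machine
(regularization constant C = 1.0 by default, exposed in the config).
Because samples are far fewer than genes, each fit is solved in the dual
over the e × e gram matrix of the standardized expression values (libsvm's
SMO), and the primal weights are recovered as w = Xᵀ(α ⊙ y) from the
support coefficients. Within one recursive step the gram matrix is shared
across the whole ensemble — only the flipped labels differ — which makes
the ensemble essentially as cheap as a single fit. Multi-class problems
use one-vs-rest: one weight row per class, each row normalised to unit
1-norm, and the sum of squares in step 3 runs over rows as well as
members, preserving the aggregation's semantics. Degenerate label flips
(all one class) are redrawn, at most 10 times.

**Randomness.** Every routine takes a `numpy.random.Generator`; a single
top-level seed drives label flips, SMOTE draws, bootstrap draws and fold
shuffling in sequence, so any reported run is reproducible bit-for-bit
from its seed.

## Evaluation protocols

- **Stability.** Run the selector `runs` times (default 10), each time on
  round(0.8·e) samples drawn with replacement (a without-replacement flag
  exists because "80% resampling" is ambiguous). For each x in
  {50, 100, 150, 200} record the top-x lists and average the Jaccard index
  |A∩B|/|A∪B| over all runs·(runs−1)/2 unordered pairs — 45 pairs for 10
  runs. An x larger than the ranked gene count is clamped with a warning.
- **Accuracy.** Restrict the matrix to the selected genes and run
  stratified 10-fold cross-validation (stratified to avoid empty-class
  folds at these sample sizes) with a linear SVM, random forest or k-NN;
  the per-fold score is informedness (Youden's J) = sensitivity +
  specificity − 1, macro-averaged one-vs-rest for multi-class problems —
  a reduction chosen because it collapses to the plain binary formula at
  two classes.
- **Gain.** Relative improvement (p′ − p″)/p″ of one metric value over a
  baseline, reported as a fraction (×100 for percent). Reported values are
  rounded to 2 decimals; full precision is kept internally.
- **Weight-dispersion diagnostic.** Train one noise-perturbed ensemble on
  the full data and compute, per gene, the coefficient of variation
  c_v = σ/μ (sample SD) of its absolute normalised weight across members.
  Genes that truly discriminate hold their weight under label noise (low
  c_v); irrelevant genes fluctuate around small means (high c_v). The
  package asserts only the directional contrast between the 10 highest-
  and 10 lowest-importance genes.

## Synthetic data

The generator emulates the microarray regime of the benchmark panels
(e ≪ n, default 60 samples × 2000 genes, two or more classes, optional
imbalance). k informative genes get class-conditional means shifted by
`effect_size` within-class SDs between adjacent classes. Each informative
gene is followed by `block_size` companions formed as signal + independent
Gaussian noise whose variance v is calibrated analytically from the target
within-class correlation r via r = 1/√(1+v) — chosen over covariance
factorization for transparency. Remaining genes are pure N(0, σ²) noise.
Because companions share the class signal, their pooled correlation is
slightly above the within-class target; tests therefore check the realized
mean against the target with a 0.03 margin.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heavy-tailed or log-normal intensity distributions, gene-gene
correlation outside planted blocks, and RNA-seq count noise. Passing tests
therefore demonstrate algorithmic correctness and the claimed stability
contrasts under a Gaussian shared-signal model, not performance on any
particular real dataset.

## Experiment scales used in tests and the acceptance script

Planted-gene recovery runs at 60 × 1000 with 10 informative genes (effect
2 SD, blocks of 3 at r = 0.95) over 10 seeds; the stability and
weight-dispersion contrasts run at 60 × 500 with 10 informative genes at
effect 1.5 SD over 10 experiment seeds, 10 resampled runs each. These
desk-scale regimes mirror the smallest benchmark dataset (60 samples,
2000 genes, 2 classes) while keeping a full test cycle in minutes on one
core.

## Known limitations

- The signed correlation threshold (the method as stated) leaves strongly
  anti-correlated redundancy in place unless `absolute` mode is chosen.
- With λ close to the typical noise correlation the pruning graph becomes
  dense and leader extraction quadratic-to-quartic; λ = 0.9 keeps it
  sparse on realistic data.
- Rank aggregation by sums is sensitive to a single catastrophic run; no
  robust (median/trimmed) variant is provided.
- The hinge-loss dual and a squared-hinge primal solver give slightly
  different weight vectors; rankings agree on well-separated data but can
  differ at near-ties. The package fixes one convention (hinge, dual) and
  tests against libsvm's explicit linear kernel as the independent route.
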