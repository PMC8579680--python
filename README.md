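# rsgsa — robust and stable gene selection

`rsgsa` is a supervised gene selector for expression matrices in the
small-sample regime (tens of samples, thousands of genes), built for
studies where the *identity* of the selected genes matters as much as the
classification accuracy they achieve: biomarker panels are only credible
if re-running the selector on slightly perturbed data returns essentially
the same genes.

It implements a two-stage algorithm:

1. **Correlation pruning.** Build a graph with one node per gene and an
   edge wherever Pearson r ≥ λ (default 0.9). Repeatedly take the node
   with the highest eigenvector centrality across all connected components
   as a *leader*, prune its neighbours as redundant *members*, and delete
   them, until no edge remains. Leaders are an independent set of the
   graph; members are reported alongside their leader so no gene is lost.
2. **Stable SVM-RFE.** Rank the leaders by recursive feature elimination
   where each recursive step trains an ensemble of |L| linear SVMs (default
   10) under small label-flip noise (f = 0.03), normalises each weight
   vector to unit 1-norm (w′ = w / Σᵢ|wᵢ|), scores genes by the ensemble
   sum of squares Wᵣⁱ = Σₗ(w′ₗⁱ)², and drops the lowest-scoring 10% of
   survivors. The whole recursion is repeated on m bootstrap resamples
   (default 10) and the rankings are combined by rank sums sʲ = Σᵢ sᵢʲ.
   Imbalanced classes are balanced up front by synthetic minority
   oversampling (interpolation, not duplication).

The package also ships the matching evaluation protocols — stability as
the mean pairwise Jaccard index of top-X lists over repeated 80%
resamplings, accuracy as informedness (Youden's J = sensitivity +
specificity − 1) under stratified 10-fold cross-validation, relative gain
(p′ − p″)/p″, and the per-gene coefficient-of-variation diagnostic of
ensemble weights — plus a synthetic-data generator that plants known
informative genes and correlated blocks for testing. See
`docs/methods.md` for the full model description.

## Worked example

Simulate a 60 × 2000 two-class dataset with 10 informative genes (class
shift 2 SD), each followed by 3 companions correlated at r ≈ 0.95, then
rank:

```
$ rsgsa simulate --samples 60 --genes 2000 --informative 10 --block 3 \
      --effect 2.0 --seed 7 --out fixtures/
wrote 60 x 2000 fixture to fixtures/

$ rsgsa rank --input fixtures/expression.tsv --labels-col class \
      --lambda 0.9 --ensemble 10 --noise 0.03 --bootstraps 10 \
      --target 50 --seed 7 --out ranking.tsv
INFO rsgsa: leader extraction: 2000 genes -> 1970 leaders (30 pruned)
INFO rsgsa: ranking 1970 leader genes over 10 bootstrap runs
ranked 1970 leader genes (30 pruned) -> ranking.tsv

$ head -6 ranking.tsv
rank    gene_id  aggregated_rank_sum  members
0       g00020   47                   g00021;g00022;g00023
1       g00008   52                   g00009;g00010;g00011
2       g00016   57                   g00017;g00018;g00019
3       g00004   62                   g00005;g00006;g00007
4       g00000   70                   g00001;g00002;g00003
```

All 30 planted companions were absorbed as members of their informative
leader (2000 → 1970 genes), and the ten planted genes occupy ranks 0–9.
`rank` is 0-based with 0 the most important gene; `aggregated_rank_sum` is
the rank sum sʲ over the 10 bootstrap runs (smaller = consistently ranked
near the top — the first noise gene, at rank 10, already jumps to a rank
sum of 610 versus 150 for the last planted gene); `members` lists the
correlated genes pruned with that leader. The evaluation protocol on the
same data,

```
$ rsgsa evaluate --input fixtures/expression.tsv --labels-col class \
      --runs 10 --sample-frac 0.8 --top 50,100 --classifier lsvm \
      --folds 10 --seed 7 --out report.tsv
$ cat report.tsv
x    JI_avg  I_avg  classifier  runs  seed
50   0.17    1.00   lsvm        10    7
100  0.15    1.00   lsvm        10    7
```

reports, per top-X size, the mean pairwise Jaccard index over the 45
unordered pairs of 10 resampled runs (`JI_avg`) and the mean 10-fold CV
informedness of a linear SVM on the top-X genes (`I_avg`, here 1.00: the
planted signal separates the classes perfectly).

The same functionality is available as a library:

```python
import numpy as np
from rsgsa import EnsembleConfig, SyntheticSpec, generate, rsgsa

dataset, truth = generate(SyntheticSpec(seed=7))
ranking, assignment = rsgsa(dataset, lam=0.9, config=EnsembleConfig(),
                            rng=np.random.default_rng(7))
print(ranking.top(10))
```

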