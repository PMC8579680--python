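"""Stable SVM-RFE with bootstrap rank aggregation.

Stage two of the selector. Classical SVM-RFE ranks genes by recursively
training a linear SVM and discarding the genes with the smallest squared
weights. The stabilised variant used here perturbs each recursive step: an
ensemble of linear SVMs is trained, each on the same data but with a small
fraction of class labels flipped at random. Each member's weight vector
w_l is normalised to unit 1-norm,

    w_l' = w_l / sum_i |w_l^i|,

and the per-gene importance of step r is the ensemble sum of squares,

    W_r^i = sum_l (w_l'^i)^2,

so a gene must carry weight consistently across the perturbed fits to
survive. The whole recursion is wrapped in m full-size bootstrap resamples
of the training examples; each run emits an integer ranking s_i (rank 0 =
most important) and the final order is by rank sums

    s^j = sum_i s_i^j.

Imbalanced inputs are balanced once, up front, by synthetic minority
oversampling (interpolation between minority neighbours, not duplication).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import _libsvm as libsvm

libsvm.set_verbosity_wrap(0)

from .correlation_pruning import LeaderAssignment, build_graph, extract_leaders, prune_dataset
from .expression_io import ExpressionDataset

logger = logging.getLogger("rsgsa")

__all__ = [
    "EnsembleConfig",
    "WeightVector",
    "RunRanking",
    "AggregatedRanking",
    "flip_labels",
    "balance_classes",
    "train_weight_vector",
    "aggregate_weights",
    "ssvm_rfe_rank",
    "bootstrap_sample",
    "aggregate_ranks",
    "rsgsa",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunable parameters of the stable recursive elimination.

    Defaults follow the method's stated operating point: an ensemble of 10
    linear SVMs per recursive step, 3% label-flip noise, 10 bootstrap runs,
    10% of surviving genes dropped per step down to a 50-gene target.
    """

    ensemble_size: int = 10
    noise_fraction: float = 0.03
    elimination_fraction: float = 0.10
    target_gene_count: int = 50
    bootstrap_runs: int = 10
    bootstrap_fraction: float = 1.0
    svm_regularization: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not 0.0 <= self.noise_fraction < 0.5:
            raise ValueError("noise_fraction must lie in [0, 0.5)")
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination_fraction must lie in (0, 1)")
        if self.target_gene_count < 1:
            raise ValueError("target_gene_count must be >= 1")
        if self.bootstrap_runs < 1:
            raise ValueError("bootstrap_runs must be >= 1")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")
        if self.svm_regularization <= 0:
            raise ValueError("svm_regularization must be positive")


@dataclass
class WeightVector:
    """One ensemble member's linear-SVM weights.

    ``raw`` and ``normalized`` have shape (n_classifiers, n_genes): one row
    for binary problems, one row per class (one-vs-rest) otherwise. Each
    normalised row has unit 1-norm.
    """

    raw: np.ndarray
    normalized: np.ndarray
    ensemble_index: int = 0
    step: int = 0


@dataclass
class RunRanking:
    """Full gene permutation from one bootstrap run (rank 0 = best).

    ``first_step_importance`` is the aggregated importance W_1 computed
    while all genes were still present — the one step shared by every run —
    kept for tie-breaking during aggregation.
    """

    ranks: np.ndarray  # ranks[j] = rank of gene j, a permutation of 0..n-1
    gene_ids: List[str]
    run_index: int = 0
    first_step_importance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        n = len(self.gene_ids)
        if sorted(self.ranks.tolist()) != list(range(n)):
            raise ValueError("ranks must be a permutation of 0..n-1")


@dataclass
class AggregatedRanking:
    """Rank sums over m runs with the final gene order."""

    gene_ids: List[str]
    rank_sums: np.ndarray  # aligned with gene_ids
    order: List[int]  # positions into gene_ids, best first
    n_runs: int

    @property
    def ordered_gene_ids(self) -> List[str]:
        return [self.gene_ids[i] for i in self.order]

    def rank_sum_of(self, gene_id: str) -> int:
        return int(self.rank_sums[self.gene_ids.index(gene_id)])

    def top(self, x: int) -> List[str]:
        return self.ordered_gene_ids[:x]


# ---------------------------------------------------------------------------
# label perturbation and class balancing
# ---------------------------------------------------------------------------

def flip_labels(
    labels: Sequence, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip round(f * e) labels, each to a different class chosen uniformly.

    Positions are drawn uniformly without replacement; a flipped position
    never keeps its original class.
    """
    labels = np.asarray(labels, dtype=object)
    if f < 0 or f >= 0.5:
        raise ValueError("noise fraction must lie in [0, 0.5)")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to flip labels")
    e = len(labels)
    k = int(round(f * e))
    if k == 0:
        return labels.copy()
    out = labels.copy()
    positions = rng.choice(e, size=k, replace=False)
    for pos in positions:
        others = [c for c in classes if c != labels[pos]]
        out[pos] = others[rng.integers(len(others))]
    return out


def balance_classes(
    dataset: ExpressionDataset,
    rng: np.random.Generator,
    k_neighbors: int = 5,
) -> ExpressionDataset:
    """Oversample minority classes to the majority count (SMOTE).

    Each synthetic sample is x + u * (x_nn - x) for a minority sample x,
    one of its k nearest minority neighbours x_nn (k capped at minority
    size - 1) and u ~ Uniform[0, 1]. A singleton minority class cannot be
    interpolated and falls back to jittered duplication (Gaussian noise at
    1% of the per-gene standard deviation) with a warning.
    """
    labels = dataset.labels
    classes, counts = np.unique(labels.astype(str), return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to balance")
    majority = counts.max()
    if (counts == majority).all():
        return dataset

    global_sd = dataset.values.std(axis=0)
    new_rows: List[np.ndarray] = []
    new_labels: List = []
    for cls, count in zip(classes, counts):
        deficit = int(majority - count)
        if deficit == 0:
            continue
        idx = np.where(labels.astype(str) == cls)[0]
        X = dataset.values[idx]
        if len(idx) == 1:
            logger.warning(
                "class %r has a single sample: jittered duplication used",
                cls,
            )
            for _ in range(deficit):
                new_rows.append(
                    X[0] + rng.normal(0.0, 0.01 * global_sd, size=X.shape[1])
                )
                new_labels.append(labels[idx[0]])
            continue
        k = min(k_neighbors, len(idx) - 1)
        # pairwise distances within the minority class
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]
        for _ in range(deficit):
            i = int(rng.integers(len(idx)))
            j = int(nn[i, rng.integers(k)])
            u = rng.uniform()
            new_rows.append(X[i] + u * (X[j] - X[i]))
            new_labels.append(labels[idx[0]])

    values = np.vstack([dataset.values, np.asarray(new_rows)])
    labels_out = np.concatenate([dataset.labels, np.asarray(new_labels,
                                                            dtype=object)])
    sample_ids = None
    if dataset.sample_ids is not None:
        sample_ids = list(dataset.sample_ids) + [
            f"synth{i}" for i in range(len(new_rows))
        ]
    return ExpressionDataset(
        values=values, labels=labels_out,
        gene_ids=list(dataset.gene_ids), sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# SVM training and weight aggregation
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0  # constant gene: leave it centred at 0
    return (values - mu) / sd


def _fit_binary_svm_gram(
    X: np.ndarray, gram: np.ndarray, y01: np.ndarray, C: float
) -> np.ndarray:
    """Primal weights of a binary hinge-loss linear SVM from its gram dual.

    Because e << n, the maximum-margin problem is solved in its dual over
    the e x e gram matrix (libsvm's SMO, called through its low-level
    binding to avoid per-fit estimator overhead in the recursion's hot
    loop); the weights are recovered as w = X[support].T @ dual_coef.
    libsvm orients its decision function toward the label seen first in
    y, so the weights are flipped when needed to point toward class 1.
    """
    # max_iter caps rare SMO cycling on bootstrap resamples where
    # duplicated samples carry contradictory (flipped) labels; typical
    # fits here converge in well under 100 iterations
    support, _, _, sv_coef, *_rest = libsvm.fit(
        gram, y01, svm_type=0, kernel="precomputed", C=C, tol=1e-3,
        max_iter=100_000,
    )
    w = sv_coef.ravel() @ X[support]
    return w if y01[0] == 1.0 else -w


def _fit_linear_svm_gram(
    X: np.ndarray, gram: np.ndarray, y: np.ndarray, C: float
) -> np.ndarray:
    """Weight rows of a (one-vs-rest) linear SVM fitted via its gram matrix.

    Binary problems give one row, oriented so positive weights vote for
    the lexicographically larger class; k-class problems give k
    one-vs-rest rows, each oriented so positive weights vote for its
    class.
    """
    classes = sorted(set(y))
    gram = np.ascontiguousarray(gram, dtype=np.float64)
    if len(classes) == 2:
        y01 = np.where(y == classes[1], 1.0, 0.0)
        return _fit_binary_svm_gram(X, gram, y01, C)[None, :]
    rows = [
        _fit_binary_svm_gram(X, gram, np.where(y == cls, 1.0, 0.0), C)
        for cls in classes
    ]
    return np.vstack(rows)


def _flip_until_valid(
    labels: np.ndarray, noise_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip labels, redrawing (max 10x) if only one class survives."""
    if noise_fraction == 0:
        return labels
    for _ in range(10):
        y = flip_labels(labels, noise_fraction, rng)
        if len(set(y)) >= 2:
            return y
    raise RuntimeError(
        "label flipping degenerated to a single class 10 times"
    )


def _normalize_rows(raw: np.ndarray) -> np.ndarray:
    norms = np.abs(raw).sum(axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return raw / norms


def train_weight_vector(
    dataset: ExpressionDataset,
    rng: np.random.Generator,
    noise_fraction: float = 0.03,
    C: float = 1.0,
    ensemble_index: int = 0,
    step: int = 0,
) -> WeightVector:
    """Train one noise-perturbed linear SVM and return normalised weights.

    Expression values are z-scored per gene; labels are perturbed by
    :func:`flip_labels`. Multi-class problems use one-vs-rest, giving one
    weight row per class; every row is normalised to unit 1-norm. A flip
    that degenerates the labels to a single class is redrawn (max 10
    attempts).
    """
    X = _standardize(dataset.values)
    y = _flip_until_valid(
        dataset.labels, noise_fraction, rng
    ).astype(str)
    gram = X @ X.T
    raw = _fit_linear_svm_gram(X, gram, y, C)
    return WeightVector(raw=raw, normalized=_normalize_rows(raw),
                        ensemble_index=ensemble_index, step=step)


def _train_ensemble(
    dataset: ExpressionDataset,
    rng: np.random.Generator,
    ensemble_size: int,
    noise_fraction: float,
    C: float,
    step: int,
) -> List[WeightVector]:
    """Train one recursive step's ensemble, sharing the gram matrix.

    The expression matrix is identical across members — only the flipped
    labels differ — so the e x e gram is computed once per step.
    """
    X = _standardize(dataset.values)
    gram = X @ X.T
    vectors = []
    for l in range(ensemble_size):
        y = _flip_until_valid(
            dataset.labels, noise_fraction, rng
        ).astype(str)
        raw = _fit_linear_svm_gram(X, gram, y, C)
        vectors.append(WeightVector(
            raw=raw, normalized=_normalize_rows(raw),
            ensemble_index=l, step=step,
        ))
    return vectors


def aggregate_weights(vectors: Sequence[WeightVector]) -> np.ndarray:
    """Per-gene ensemble importance: sum of squared normalised weights.

    Sums over both ensemble members and (for multi-class) one-vs-rest rows,
    preserving the sum-of-squares semantics; the result is nonnegative and
    invariant to a global sign flip of any member's weights.
    """
    if not vectors:
        raise ValueError("no weight vectors to aggregate")
    n = vectors[0].normalized.shape[1]
    for v in vectors:
        if v.normalized.shape[1] != n:
            raise ValueError("weight vectors have mismatched lengths")
    W = np.zeros(n)
    for v in vectors:
        W += (v.normalized ** 2).sum(axis=0)
    return W


# ---------------------------------------------------------------------------
# recursive elimination and bootstrap aggregation
# ---------------------------------------------------------------------------

def ssvm_rfe_rank(
    dataset: ExpressionDataset,
    config: EnsembleConfig,
    rng: np.random.Generator,
    run_index: int = 0,
) -> RunRanking:
    """One stable recursive-elimination pass -> full gene permutation.

    Each step trains ``ensemble_size`` perturbed SVMs on the surviving
    genes, aggregates importances, and drops
    max(1, ceil(elimination_fraction * surviving)) genes with the lowest
    importance (never dropping below ``target_gene_count``). Survivors get
    ranks 0..k-1 by descending final importance; eliminated genes follow in
    reverse elimination order, within one step by descending importance at
    elimination time. Ties break toward the lower gene index.
    """
    n = dataset.n_genes
    surviving = list(range(n))
    eliminated_batches: List[List[int]] = []  # in elimination order
    first_step_importance: Optional[np.ndarray] = None
    final_W: Optional[np.ndarray] = None
    step = 0

    while True:
        step += 1
        sub = dataset.select_genes(surviving)
        vectors = _train_ensemble(
            sub, rng, config.ensemble_size, config.noise_fraction,
            config.svm_regularization, step,
        )
        W = aggregate_weights(vectors)
        if first_step_importance is None:
            first_step_importance = W.copy()
        if len(surviving) <= config.target_gene_count:
            final_W = W
            break
        n_drop = max(1, math.ceil(config.elimination_fraction
                                  * len(surviving)))
        n_drop = min(n_drop, len(surviving) - config.target_gene_count)
        # order survivors by (-importance, index): the tail gets dropped
        order = sorted(range(len(surviving)),
                       key=lambda i: (-W[i], surviving[i]))
        dropped_local = order[len(surviving) - n_drop:]
        # record in descending importance at elimination time
        batch = [surviving[i] for i in dropped_local]
        eliminated_batches.append(batch)
        kept = sorted(set(range(len(surviving))) - set(dropped_local))
        surviving = [surviving[i] for i in kept]
        if len(surviving) <= config.target_gene_count:
            # rank the survivors with one more ensemble round
            sub = dataset.select_genes(surviving)
            vectors = _train_ensemble(
                sub, rng, config.ensemble_size, config.noise_fraction,
                config.svm_regularization, step + 1,
            )
            final_W = aggregate_weights(vectors)
            break

    assert final_W is not None
    ranks = np.empty(n, dtype=int)
    survivor_order = sorted(
        range(len(surviving)), key=lambda i: (-final_W[i], surviving[i])
    )
    next_rank = 0
    for i in survivor_order:
        ranks[surviving[i]] = next_rank
        next_rank += 1
    for batch in reversed(eliminated_batches):
        for gene in batch:
            ranks[gene] = next_rank
            next_rank += 1
    return RunRanking(
        ranks=ranks, gene_ids=list(dataset.gene_ids), run_index=run_index,
        first_step_importance=first_step_importance,
    )


def bootstrap_sample(
    dataset: ExpressionDataset,
    rng: np.random.Generator,
    fraction: float = 1.0,
) -> ExpressionDataset:
    """Resample round(fraction * e) examples uniformly with replacement.

    A resample that loses a class entirely is redrawn (max 10 attempts).
    """
    e = dataset.n_samples
    size = max(1, int(round(fraction * e)))
    required = set(np.unique(dataset.labels.astype(str)))
    for _ in range(10):
        idx = rng.integers(0, e, size=size)
        drawn = set(np.unique(dataset.labels[idx].astype(str)))
        if drawn == required or len(required) < 2:
            return dataset.select_samples(idx.tolist())
    raise RuntimeError("bootstrap kept missing a class after 10 redraws")


def aggregate_ranks(runs: Sequence[RunRanking]) -> AggregatedRanking:
    """Sum per-run ranks (Eq-style rank aggregation) and order genes.

    Final order ascends by rank sum; ties break by the mean first-step
    importance across runs (higher first), then by gene index.
    """
    if not runs:
        raise ValueError("no runs to aggregate")
    gene_ids = runs[0].gene_ids
    for run in runs[1:]:
        if run.gene_ids != gene_ids:
            raise ValueError("runs rank inconsistent gene sets")
    sums = np.zeros(len(gene_ids), dtype=int)
    for run in runs:
        sums += run.ranks
    imp = np.zeros(len(gene_ids))
    n_with_imp = 0
    for run in runs:
        if run.first_step_importance is not None:
            imp += run.first_step_importance
            n_with_imp += 1
    if n_with_imp:
        imp /= n_with_imp
    order = sorted(range(len(gene_ids)),
                   key=lambda j: (sums[j], -imp[j], j))
    return AggregatedRanking(
        gene_ids=list(gene_ids), rank_sums=sums, order=order,
        n_runs=len(runs),
    )


def rsgsa(
    dataset: ExpressionDataset,
    lam: float = 0.9,
    config: Optional[EnsembleConfig] = None,
    rng: Optional[np.random.Generator] = None,
    corr_mode: str = "signed",
) -> Tuple[AggregatedRanking, LeaderAssignment]:
    """Run the full two-stage selector.

    Pipeline: balance classes -> correlation-graph leader extraction at
    threshold ``lam`` -> m bootstrap resamples, each ranked by stable
    SVM-RFE -> rank-sum aggregation. Returns the aggregated ranking over
    leader genes plus the leader -> pruned-members map.
    """
    config = config or EnsembleConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    balanced = balance_classes(dataset, rng)
    graph = build_graph(balanced, lam=lam, mode=corr_mode)
    assignment = extract_leaders(graph)
    pruned = prune_dataset(balanced, assignment)
    logger.info(
        "ranking %d leader genes over %d bootstrap runs",
        pruned.n_genes, config.bootstrap_runs,
    )
    runs = []
    for i in range(config.bootstrap_runs):
        resample = bootstrap_sample(pruned, rng, config.bootstrap_fraction)
        runs.append(ssvm_rfe_rank(resample, config, rng, run_index=i))
    ranking = aggregate_ranks(runs)
    return ranking, assignment
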