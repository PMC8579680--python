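"""Stability and accuracy evaluation of gene selectors.

Stability is measured as the average pairwise Jaccard index of the top-X
gene lists produced by repeated runs of a selector on resampled data
(10 runs -> 45 unordered pairs). Accuracy is measured as informedness
(Youden's J: sensitivity + specificity - 1) under stratified k-fold
cross-validation on the data restricted to the selected genes. Gain is the
relative improvement (p' - p'') / p'' of one metric value over a baseline.
The coefficient of variation sigma/mu of per-gene ensemble weights serves
as a per-gene stability diagnostic: genes that matter hold their weight
across noise-perturbed fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from .expression_io import ExpressionDataset
from .stable_rfe import train_weight_vector

logger = logging.getLogger("rsgsa")

__all__ = [
    "ConfusionSummary",
    "EvaluationReport",
    "jaccard",
    "informedness",
    "gain",
    "coefficient_of_variation",
    "stability_experiment",
    "accuracy_experiment",
    "ensemble_weight_dispersion",
]

DEFAULT_TOP_X = (50, 100, 150, 200)


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class EvaluationReport:
    """Per-top-X stability (and optionally accuracy) summary."""

    jaccard_by_x: Dict[int, float]
    top_lists_by_x: Dict[int, List[List[str]]]
    n_runs: int
    informedness_by_x: Dict[int, float] = field(default_factory=dict)
    #: unordered run pairs actually compared per top-X Jaccard average
    n_pairs: int = 0


def jaccard(a: Sequence, b: Sequence) -> float:
    """|A ∩ B| / |A ∪ B| for two gene sets."""
    A, B = set(a), set(b)
    if not A and not B:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(A & B) / len(A | B)


def informedness(c: ConfusionSummary) -> float:
    """Sensitivity + specificity - 1 (ranges -1..+1; +1 = fully informed)."""
    if c.tp + c.fn == 0:
        raise ValueError("no positive examples (TP + FN == 0)")
    if c.fp + c.tn == 0:
        raise ValueError("no negative examples (FP + TN == 0)")
    return c.tp / (c.tp + c.fn) - c.fp / (c.fp + c.tn)


def gain(p_new: float, p_base: float) -> float:
    """Relative improvement (p' - p'') / p'' as a fraction (x100 for %)."""
    if p_base <= 0:
        raise ValueError("baseline metric must be positive")
    return (p_new - p_base) / p_base


def coefficient_of_variation(samples: Sequence[float]) -> float:
    """sigma / mu with the sample (n-1) standard deviation."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    if mu == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mu)


# ---------------------------------------------------------------------------
# experimental protocols
# ---------------------------------------------------------------------------

def stability_experiment(
    dataset: ExpressionDataset,
    selector: Callable[[ExpressionDataset, np.random.Generator], List[str]],
    runs: int = 10,
    sample_frac: float = 0.8,
    top_x: Sequence[int] = DEFAULT_TOP_X,
    rng: Optional[np.random.Generator] = None,
    with_replacement: bool = True,
) -> EvaluationReport:
    """Average pairwise Jaccard of top-X lists over resampled runs.

    Each run draws round(sample_frac * e) samples (with replacement by
    default), hands the resample to ``selector`` (which returns genes
    ordered best-first) and records the top-x prefix for every x. The
    stability score for x is the mean Jaccard over all runs*(runs-1)/2
    unordered list pairs — 45 pairs for the standard 10 runs.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs for pairwise comparison")
    if not 0.0 < sample_frac <= 1.0:
        raise ValueError("sample_frac must lie in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)

    e = dataset.n_samples
    size = max(1, int(round(sample_frac * e)))
    required = set(np.unique(dataset.labels.astype(str)))
    orderings: List[List[str]] = []
    for _ in range(runs):
        for _attempt in range(10):
            if with_replacement:
                idx = rng.integers(0, e, size=size)
            else:
                idx = rng.choice(e, size=size, replace=False)
            if set(np.unique(dataset.labels[idx].astype(str))) == required:
                break
        resample = dataset.select_samples([int(i) for i in idx])
        orderings.append(list(selector(resample, rng)))

    n_ranked = min(len(o) for o in orderings)
    jaccard_by_x: Dict[int, float] = {}
    top_lists_by_x: Dict[int, List[List[str]]] = {}
    n_pairs = 0
    for x in top_x:
        if x > n_ranked:
            warnings.warn(
                f"top-{x} exceeds the {n_ranked} ranked genes; clamped",
                stacklevel=2,
            )
        xx = min(x, n_ranked)
        tops = [o[:xx] for o in orderings]
        pair_scores = [
            jaccard(tops[i], tops[j])
            for i in range(runs) for j in range(i + 1, runs)
        ]
        jaccard_by_x[x] = float(np.mean(pair_scores))
        top_lists_by_x[x] = tops
        n_pairs = len(pair_scores)
    return EvaluationReport(
        jaccard_by_x=jaccard_by_x, top_lists_by_x=top_lists_by_x,
        n_runs=runs, n_pairs=n_pairs,
    )


def _macro_informedness(y_true: np.ndarray, y_pred: np.ndarray,
                        classes: Sequence[str]) -> float:
    """One-vs-rest informedness averaged over classes.

    Reduces to the plain binary formula when there are two classes (both
    one-vs-rest terms are then equal).
    """
    scores = []
    for cls in classes:
        pos = y_true == cls
        pred_pos = y_pred == cls
        tp = int(np.sum(pos & pred_pos))
        fn = int(np.sum(pos & ~pred_pos))
        fp = int(np.sum(~pos & pred_pos))
        tn = int(np.sum(~pos & ~pred_pos))
        scores.append(informedness(ConfusionSummary(tp, fn, fp, tn)))
    return float(np.mean(scores))


def _make_classifier(name: str, seed: int):
    if name in ("lsvm", "linear-svm"):
        return LinearSVC(C=1.0, dual=False, random_state=seed,
                         max_iter=20000)
    if name in ("rf", "random-forest"):
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name in ("knn", "k-nn"):
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier: {name!r}")


def accuracy_experiment(
    dataset: ExpressionDataset,
    top_genes: Sequence[str],
    folds: int = 10,
    classifier: str = "lsvm",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean informedness over stratified k-fold CV on the selected genes.

    The expression matrix is restricted to ``top_genes``; per fold the
    classifier is trained on the remaining folds (z-scored using
    training-fold statistics) and informedness is computed on the held-out
    fold (macro one-vs-rest for multi-class problems).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    classes, counts = np.unique(dataset.labels.astype(str),
                                return_counts=True)
    small = [str(c) for c, n in zip(classes, counts) if n < folds]
    if small:
        raise ValueError(
            f"class(es) {', '.join(small)} have fewer than {folds} samples; "
            f"use fewer folds"
        )
    id_to_col = {g: i for i, g in enumerate(dataset.gene_ids)}
    cols = [id_to_col[g] for g in top_genes]
    X_all = dataset.values[:, cols]
    y_all = dataset.labels.astype(str)

    seed = int(rng.integers(2**31 - 1))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X_all, y_all):
        mu = X_all[train_idx].mean(axis=0)
        sd = X_all[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        clf = _make_classifier(classifier, seed)
        clf.fit((X_all[train_idx] - mu) / sd, y_all[train_idx])
        y_pred = clf.predict((X_all[test_idx] - mu) / sd)
        scores.append(_macro_informedness(y_all[test_idx], y_pred,
                                          list(classes)))
    return float(np.mean(scores))


def ensemble_weight_dispersion(
    dataset: ExpressionDataset,
    ensemble_size: int = 10,
    noise_fraction: float = 0.03,
    C: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, np.ndarray]:
    """Per-gene weight dispersion across one noise-perturbed ensemble.

    Trains ``ensemble_size`` label-flip-perturbed linear SVMs on the full
    data (one recursive stage) and returns, per gene, the mean, standard
    deviation (n-1) and coefficient of variation of the absolute normalised
    weights summed over one-vs-rest rows. Important genes hold their weight
    across the perturbed fits, so their CV is low; noise genes show large
    relative dispersion.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    weights = []
    for l in range(ensemble_size):
        wv = train_weight_vector(dataset, rng, noise_fraction, C=C,
                                 ensemble_index=l)
        weights.append(np.abs(wv.normalized).sum(axis=0))
    W = np.vstack(weights)  # ensemble_size x n_genes
    mu = W.mean(axis=0)
    sigma = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sigma / mu, np.inf)
    return {"mean": mu, "sd": sigma, "cv": cv}
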