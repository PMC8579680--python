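"""Synthetic expression data with planted ground truth.

Emulates the small-e, large-n microarray regime (tens of samples, hundreds
to thousands of genes): a handful of *informative* genes whose class-
conditional means are shifted by a chosen effect size, each optionally
accompanied by a block of *companion* genes correlated with it at a target
Pearson r, and a sea of pure-noise genes. Ground truth (which genes are
informative, which belong to which block) is returned alongside, so every
pipeline stage can be tested without any external download.

The correlation inside a block is induced by sharing the informative
gene's signal and adding independent Gaussian noise of variance v relative
to the signal's within-class variance, which gives an expected within-class
correlation r = 1 / sqrt(1 + v); the noise scale is calibrated
analytically as v = 1/r^2 - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .expression_io import ExpressionDataset, write_expression

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic expression generator.

    ``effect_size`` is the between-adjacent-class mean shift in units of
    the within-class standard deviation ``noise_sd``; ``block_size`` is the
    number of correlated companions planted per informative gene;
    ``within_block_corr`` is the target within-class Pearson r between a
    companion and its informative gene.
    """

    n_samples: int = 60
    n_genes: int = 2000
    n_informative: int = 10
    block_size: int = 3
    effect_size: float = 2.0
    within_block_corr: float = 0.95
    n_classes: int = 2
    class_proportions: Optional[Sequence[float]] = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative * (1 + self.block_size) > self.n_genes:
            raise ValueError(
                "n_informative * (1 + block_size) exceeds n_genes"
            )
        if not 0.0 < self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.class_proportions is not None:
            props = list(self.class_proportions)
            if len(props) != self.n_classes:
                raise ValueError("class_proportions length != n_classes")
            if abs(sum(props) - 1.0) > 1e-9 or min(props) <= 0:
                raise ValueError("class_proportions must be positive and "
                                 "sum to 1")


@dataclass
class GroundTruth:
    """Which planted genes carry signal, and their correlated blocks."""

    informative: List[str]
    blocks: Dict[str, List[str]]  # informative gene -> companion ids


def generate(spec: SyntheticSpec) -> Tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from the generative model (reproducible from seed).

    Gene layout: informative gene i occupies one column, immediately
    followed by its ``block_size`` companions; remaining columns are pure
    noise. Labels are assigned per ``class_proportions`` (uniform by
    default) and shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    e, n = spec.n_samples, spec.n_genes
    k = spec.n_informative

    props = (list(spec.class_proportions) if spec.class_proportions
             else [1.0 / spec.n_classes] * spec.n_classes)
    counts = [int(round(p * e)) for p in props]
    counts[-1] = e - sum(counts[:-1])
    if min(counts) < 2:
        raise ValueError("class proportions leave a class with < 2 samples")
    labels = np.concatenate([
        np.full(c, f"c{ci}", dtype=object) for ci, c in enumerate(counts)
    ])
    rng.shuffle(labels)
    class_index = np.array([int(str(l)[1:]) for l in labels])

    values = np.empty((e, n))
    gene_ids = [f"g{j:05d}" for j in range(n)]
    informative: List[str] = []
    blocks: Dict[str, List[str]] = {}

    # noise-scale for companions: v = 1/r^2 - 1 gives within-class corr r
    v = 1.0 / spec.within_block_corr**2 - 1.0

    col = 0
    for i in range(k):
        mu = class_index * spec.effect_size * spec.noise_sd
        signal = mu + rng.normal(0.0, spec.noise_sd, size=e)
        values[:, col] = signal
        gid = gene_ids[col]
        informative.append(gid)
        blocks[gid] = []
        col += 1
        for _ in range(spec.block_size):
            values[:, col] = signal + rng.normal(
                0.0, spec.noise_sd * np.sqrt(v), size=e
            )
            blocks[gid].append(gene_ids[col])
            col += 1
    while col < n:
        values[:, col] = rng.normal(0.0, spec.noise_sd, size=e)
        col += 1

    dataset = ExpressionDataset(
        values=values, labels=labels, gene_ids=gene_ids,
        sample_ids=[f"s{i:03d}" for i in range(e)],
    )
    return dataset, GroundTruth(informative=informative, blocks=blocks)


def write_fixture(
    dataset: ExpressionDataset,
    ground_truth: GroundTruth,
    dir_path,
) -> None:
    """Write expression + labels + ground-truth TSVs into ``dir_path``."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    write_expression(dataset, d / "expression.tsv", label_column="class")
    with open(d / "labels.tsv", "w", encoding="utf-8") as fh:
        sample_ids = dataset.sample_ids or [
            f"s{i}" for i in range(dataset.n_samples)
        ]
        for sid, lab in zip(sample_ids, dataset.labels):
            fh.write(f"{sid}\t{lab}\n")
    with open(d / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("informative_gene\tcompanions\n")
        for gid in ground_truth.informative:
            fh.write(f"{gid}\t{';'.join(ground_truth.blocks[gid])}\n")
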