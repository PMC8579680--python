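"""Reading and writing expression matrices, labels and rankings.

All on-disk formats are plain delimited text (comma or tab, auto-detected).
The canonical in-memory orientation is samples x genes; files stored
genes-as-rows are transposed on load.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rsgsa")

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "write_ranking",
    "read_ranking",
]


@dataclass
class ExpressionDataset:
    """An e x n expression matrix with per-sample class labels.

    Parameters
    ----------
    values
        Real-valued expression levels, shape ``(e, n)`` (samples x genes).
    labels
        ``e`` categorical class identifiers (opaque strings; no ordinal
        semantics).
    gene_ids
        ``n`` pairwise-distinct gene identifier strings.
    sample_ids
        Optional ``e`` distinct sample identifiers.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        self.gene_ids = [str(g) for g in self.gene_ids]
        e, n = self.values.shape
        if len(self.labels) != e:
            raise ValueError(
                f"label count {len(self.labels)} != sample count {e}"
            )
        if len(self.gene_ids) != n:
            raise ValueError(
                f"gene id count {len(self.gene_ids)} != gene count {n}"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {', '.join(sorted(dupes))}")
        if self.sample_ids is not None and len(self.sample_ids) != e:
            raise ValueError("sample_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels))

    def select_genes(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Restrict columns to ``indices`` (order as given)."""
        idx = list(indices)
        return ExpressionDataset(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=None if self.sample_ids is None else list(self.sample_ids),
        )

    def select_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Restrict rows to ``indices`` (with repetition allowed)."""
        idx = list(indices)
        sample_ids = None
        if self.sample_ids is not None:
            # bootstrap resamples may repeat a sample; suffix repeats to
            # keep identifiers distinct
            seen: dict[str, int] = {}
            sample_ids = []
            for i in idx:
                sid = self.sample_ids[i]
                k = seen.get(sid, 0)
                seen[sid] = k + 1
                sample_ids.append(sid if k == 0 else f"{sid}.{k}")
        return ExpressionDataset(
            values=self.values[idx, :],
            labels=self.labels[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=sample_ids,
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in header else ","


def read_expression(
    path,
    orientation: str = "samples-as-rows",
    label_column: Optional[str] = None,
    label_file=None,
    missing_token: Optional[str] = None,
    missing_policy: str = "drop",
) -> ExpressionDataset:
    """Load a delimited expression matrix with class labels.

    Parameters
    ----------
    path
        CSV/TSV file with a header row and a leading identifier column.
    orientation
        ``"samples-as-rows"`` or ``"genes-as-rows"``; the latter is
        transposed so the returned dataset is always samples x genes.
    label_column
        Name of the label column inside the matrix file (samples-as-rows
        only). Exactly one of ``label_column`` / ``label_file`` is required.
    label_file
        Two-column delimited file mapping sample id -> class label.
    missing_token
        Cell value to treat as missing (e.g. ``"NA"``). Any other
        non-numeric cell raises. Missing entries trigger ``missing_policy``.
    missing_policy
        ``"drop"`` removes genes with any missing value (logged);
        ``"mean"`` imputes the per-gene mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if orientation not in ("samples-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if (label_column is None) == (label_file is None):
        raise ValueError("provide exactly one of label_column or label_file")

    sep = _sniff_delimiter(path)
    # pandas mangles duplicate header names (g1, g1.1): check the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header_fields = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = _duplicates(header_fields)
    if dupes:
        raise ValueError(f"duplicate gene ids: {', '.join(sorted(dupes))}")
    na_values = [missing_token] if missing_token is not None else []
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=na_values,
        keep_default_na=False, dtype=str,
    )
    _check_ragged(path, sep)

    labels_by_sample: Optional[dict[str, str]] = None
    if label_column is not None:
        if orientation == "genes-as-rows":
            raise ValueError(
                "label_column requires samples-as-rows; use label_file"
            )
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in header")
        label_series = df[label_column]
        df = df.drop(columns=[label_column])
    else:
        lpath = Path(label_file)
        if not lpath.exists():
            raise FileNotFoundError(f"label file not found: {lpath}")
        lsep = _sniff_delimiter(lpath)
        ldf = pd.read_csv(lpath, sep=lsep, header=None, dtype=str)
        if ldf.shape[1] != 2:
            raise ValueError("label file must have exactly 2 columns")
        # tolerate an optional header line
        labels_by_sample = dict(zip(ldf.iloc[:, 0], ldf.iloc[:, 1]))
        label_series = None

    if orientation == "genes-as-rows":
        df = df.T

    sample_ids = [str(s) for s in df.index]
    gene_ids = [str(g) for g in df.columns]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"duplicate gene ids: {', '.join(sorted(dupes))}")

    values = np.empty(df.shape, dtype=float)
    mask_missing = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy()
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                mask_missing[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric expression value {cell!r} for gene "
                    f"{gene_ids[j]!r}, sample {sample_ids[i]!r}"
                ) from None

    if mask_missing.any():
        if missing_policy == "drop":
            bad = np.where(mask_missing.any(axis=0))[0]
            logger.info(
                "dropping %d gene(s) with missing values: %s",
                len(bad), ", ".join(gene_ids[j] for j in bad),
            )
            keep = [j for j in range(len(gene_ids)) if j not in set(bad)]
            values = values[:, keep]
            gene_ids = [gene_ids[j] for j in keep]
        elif missing_policy == "mean":
            for j in np.where(mask_missing.any(axis=0))[0]:
                col = values[:, j]
                mu = np.nanmean(col)
                col[np.isnan(col)] = mu
            logger.info("imputed %d missing value(s) with per-gene means",
                        int(mask_missing.sum()))
        else:
            raise ValueError(f"unknown missing policy: {missing_policy!r}")

    if label_series is not None:
        labels = np.asarray([str(v) for v in label_series], dtype=object)
    else:
        assert labels_by_sample is not None
        missing = [s for s in sample_ids if s not in labels_by_sample]
        if missing:
            raise ValueError(
                f"label file lacks labels for samples: {', '.join(missing)}"
            )
        labels = np.asarray(
            [labels_by_sample[s] for s in sample_ids], dtype=object
        )

    if len(set(labels)) < 2:
        raise ValueError("fewer than 2 distinct class labels")
    if len(sample_ids) < 4:
        raise ValueError(f"need at least 4 samples, found {len(sample_ids)}")

    return ExpressionDataset(
        values=values, labels=labels, gene_ids=gene_ids, sample_ids=sample_ids
    )


def _check_ragged(path: Path, sep: str) -> None:
    """Raise with a line number if any data row has the wrong field count."""
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        widths = [(lineno, len(row)) for lineno, row in enumerate(reader, 1)
                  if row]
    if not widths:
        raise ValueError(f"{path}: empty file")
    header_w = widths[0][1]
    for lineno, w in widths[1:]:
        # allow R-style headers that omit the index-column name
        if w not in (header_w, header_w + 1):
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({w} fields, expected {header_w})"
            )


def write_expression(
    dataset: ExpressionDataset,
    path,
    label_column: str = "class",
    sep: str = "\t",
) -> None:
    """Write a dataset samples-as-rows with the labels as a trailing column.

    Numeric values are written at full ``repr`` precision so that a
    read -> write -> read round-trip is exact.
    """
    path = Path(path)
    sample_ids = dataset.sample_ids or [
        f"s{i}" for i in range(dataset.n_samples)
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(sep.join(["id", *dataset.gene_ids, label_column]) + "\n")
        for i in range(dataset.n_samples):
            row = [sample_ids[i]]
            row.extend(repr(float(v)) for v in dataset.values[i])
            row.append(str(dataset.labels[i]))
            fh.write(sep.join(row) + "\n")


def write_ranking(ranking, assignment, path, sep: str = "\t") -> None:
    """Write an aggregated gene ranking as a 4-column TSV.

    Columns: ``rank`` (0 = most important), ``gene_id``,
    ``aggregated_rank_sum`` and ``members`` (semicolon-joined pruned
    correlated neighbours of the leader, possibly empty). Rows ascend by
    rank.
    """
    path = Path(path)
    member_map = assignment.members_by_id
    covered = set(ranking.gene_ids)
    for leader in assignment.leaders_ids:
        if leader not in covered:
            raise ValueError(f"ranking does not cover leader {leader!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(sep.join(
            ["rank", "gene_id", "aggregated_rank_sum", "members"]) + "\n")
        for rank, gene in enumerate(ranking.ordered_gene_ids):
            members = ";".join(member_map.get(gene, []))
            fh.write(sep.join(
                [str(rank), gene, str(ranking.rank_sum_of(gene)), members]
            ) + "\n")


def read_ranking(path, sep: str = "\t") -> pd.DataFrame:
    """Load a ranking TSV written by :func:`write_ranking`."""
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "members": str},
                     keep_default_na=False)
    return df
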