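"""Correlation-graph pruning of redundant genes (leader extraction).

Stage one of the selector: build an undirected graph whose nodes are genes
and whose edges join pairs with Pearson correlation at or above a threshold
lambda (default 0.9), then repeatedly take the node with the highest
eigenvector centrality across all connected components as a *leader*,
pruning its neighbours as redundant *members*, until the graph is edge-free.
The surviving leaders are an independent set of the original graph and are
the genes handed to the ranking stage; members ride along as annotations so
no gene is lost from the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .expression_io import ExpressionDataset

logger = logging.getLogger("rsgsa")

__all__ = [
    "GeneGraph",
    "LeaderAssignment",
    "pearson_correlation",
    "build_graph",
    "eigencentrality",
    "extract_leaders",
    "prune_dataset",
]

#: numerical tolerance under which two centrality scores count as tied
TIE_TOL = 1e-12


@dataclass
class GeneGraph:
    """Undirected gene graph thresholded at ``lambda_threshold``.

    ``corr`` maps each stored edge (as a sorted index pair) to its Pearson
    r; every stored edge satisfies ``r >= lambda`` (signed mode) or
    ``|r| >= lambda`` (absolute mode).
    """

    node_ids: List[int]
    edges: Set[Tuple[int, int]]
    corr: Dict[Tuple[int, int], float]
    lambda_threshold: float
    mode: str = "signed"
    gene_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge on node {u}")
        self.edges = {(min(u, v), max(u, v)) for u, v in self.edges}

    def neighbors(self, node: int) -> Set[int]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for (u, v) in self.edges:
            g.add_edge(u, v, weight=self.corr[(u, v)])
        return g


@dataclass
class LeaderAssignment:
    """Result of leader extraction.

    ``leaders`` holds gene indices in extraction order; ``members`` maps
    each leader to the neighbours pruned with it (empty for isolated
    genes). Leaders and members together partition the original node set.
    """

    leaders: List[int]
    members: Dict[int, List[int]]
    gene_ids: Optional[List[str]] = None

    @property
    def leaders_ids(self) -> List[str]:
        if self.gene_ids is None:
            return [str(i) for i in self.leaders]
        return [self.gene_ids[i] for i in self.leaders]

    @property
    def members_by_id(self) -> Dict[str, List[str]]:
        if self.gene_ids is None:
            return {str(k): [str(m) for m in v]
                    for k, v in self.members.items()}
        return {
            self.gene_ids[k]: [self.gene_ids[m] for m in v]
            for k, v in self.members.items()
        }

    def all_nodes(self) -> Set[int]:
        nodes = set(self.leaders)
        for ms in self.members.values():
            nodes.update(ms)
        return nodes


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    A constant vector carries no co-variation signal; its correlation with
    anything is defined here as 0.0 (with a warning) so that flat genes are
    never pruned as "correlated" — the ranking stage eliminates them
    instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation defined as 0",
                      stacklevel=2)
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def build_graph(
    dataset: ExpressionDataset,
    lam: float = 0.9,
    mode: str = "signed",
) -> GeneGraph:
    """Build the thresholded correlation graph over all gene pairs.

    ``mode="signed"`` keeps edges with r >= lam (as the method is stated);
    ``mode="absolute"`` uses |r| >= lam, treating strongly anti-correlated
    genes as equally redundant.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must lie in (0, 1]")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown correlation mode: {mode!r}")

    values = dataset.values
    n = dataset.n_genes
    sd = values.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False) if n > 1 else np.ones((1, 1))
    corr = np.atleast_2d(corr)
    # constant genes: correlation to everything defined as 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)

    keep = corr >= lam if mode == "signed" else np.abs(corr) >= lam
    iu, ju = np.triu_indices(n, k=1)
    mask = keep[iu, ju]
    edges = set()
    corr_map: Dict[Tuple[int, int], float] = {}
    for u, v in zip(iu[mask], ju[mask]):
        u, v = int(u), int(v)
        edges.add((u, v))
        corr_map[(u, v)] = float(corr[u, v])
    return GeneGraph(
        node_ids=list(range(n)),
        edges=edges,
        corr=corr_map,
        lambda_threshold=lam,
        mode=mode,
        gene_ids=list(dataset.gene_ids),
    )


def _power_iteration(
    adjacency: Dict[int, Set[int]],
    nodes: List[int],
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Principal eigenvector of the 0/1 adjacency of a connected component.

    Max-norm scaling with a deterministic all-ones start. The iteration
    runs on A + I rather than A: the shift leaves every eigenvector (and
    hence the centrality ranking) unchanged while making the matrix
    primitive, so the iteration converges even on bipartite components,
    where plain power iteration oscillates with period 2.
    """
    k = len(nodes)
    pos = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((k, k))
    for node in nodes:
        i = pos[node]
        for m in adjacency[node]:
            A[i, pos[m]] = 1.0
    x = np.ones(k)
    for _ in range(max_iter):
        x_new = A @ x + x
        peak = x_new.max()
        if peak <= 0:  # no edges within the "component": defensive
            return np.ones(k)
        x_new /= peak
        if np.max(np.abs(x_new - x)) < tol:
            return x_new
        x = x_new
    return x


def eigencentrality(
    graph: GeneGraph, component: Sequence[int]
) -> Dict[int, float]:
    """Eigenvector-centrality scores of one connected component.

    Scores are the component adjacency's principal eigenvector, scaled so
    the maximum equals 1. A singleton component scores 1.
    """
    nodes = sorted(component)
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    node_set = set(nodes)
    adjacency = {
        node: graph.neighbors(node) & node_set for node in nodes
    }
    scores = _power_iteration(adjacency, nodes)
    return {node: float(s) for node, s in zip(nodes, scores)}


def _adjacency_of(graph: GeneGraph) -> Dict[int, Set[int]]:
    adj: Dict[int, Set[int]] = {node: set() for node in graph.node_ids}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def extract_leaders(graph: GeneGraph) -> LeaderAssignment:
    """Iteratively extract maximum-eigencentrality leaders.

    Each round recomputes connected components and their centralities on
    the current graph, picks the globally highest-scoring node (ties within
    ``TIE_TOL`` broken by lowest gene index), records it as a leader with
    its current neighbours as members, and deletes leader plus neighbours.
    When no edges remain, all surviving isolated nodes are appended as
    leaders with empty member lists (ascending index).
    """
    adj = _adjacency_of(graph)
    alive = set(graph.node_ids)
    leaders: List[int] = []
    members: Dict[int, List[int]] = {}

    def has_edges() -> bool:
        return any(adj[node] for node in alive)

    while has_edges():
        g = nx.Graph()
        g.add_nodes_from(sorted(alive))
        for u in alive:
            for v in adj[u]:
                g.add_edge(u, v)
        best_node, best_score = -1, -np.inf
        for comp in nx.connected_components(g):
            comp = set(comp)
            if len(comp) == 1:
                continue  # isolated nodes cannot beat hub scores of 1
            nodes = sorted(comp)
            sub_adj = {node: adj[node] & comp for node in nodes}
            scores = _power_iteration(sub_adj, nodes)
            for node, s in zip(nodes, scores):
                if s > best_score + TIE_TOL or (
                    abs(s - best_score) <= TIE_TOL and node < best_node
                ):
                    best_node, best_score = node, float(s)
        if best_node < 0:  # pragma: no cover - has_edges guarantees a hit
            break
        pruned = sorted(adj[best_node])
        leaders.append(best_node)
        members[best_node] = pruned
        for node in [best_node, *pruned]:
            for other in adj[node]:
                adj[other].discard(node)
            adj[node] = set()
            alive.discard(node)

    for node in sorted(alive):
        leaders.append(node)
        members[node] = []

    logger.info(
        "leader extraction: %d genes -> %d leaders (%d pruned)",
        len(graph.node_ids), len(leaders),
        len(graph.node_ids) - len(leaders),
    )
    return LeaderAssignment(
        leaders=leaders, members=members, gene_ids=graph.gene_ids
    )


def prune_dataset(
    dataset: ExpressionDataset, assignment: LeaderAssignment
) -> ExpressionDataset:
    """Restrict a dataset's columns to the leader genes.

    Original column order is preserved among leaders; labels are untouched.
    """
    keep = sorted(assignment.leaders)
    if keep and (keep[0] < 0 or keep[-1] >= dataset.n_genes):
        raise ValueError("assignment does not match dataset")
    return dataset.select_genes(keep)
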