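"""Phenotype-specific weighted gene-gene interaction networks.

Each PPI edge whose endpoints are both measured gets the weight
``a_ij = |cor(x_i, x_j)|**beta`` where ``cor`` is the Pearson correlation of
the endpoint expression vectors over one phenotype's samples (beta defaults
to 1). Edges with an unmeasured endpoint are dropped from the topology; the
two phenotype networks therefore share an identical node and edge set and
differ only in weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionDataset, PpiEdgeList

logger = logging.getLogger(__name__)


@dataclass
class WeightedNetwork:
    """Undirected gene network with edge weights in [0, 1].

    ``edges[k]`` is the canonical pair ``(a, b)`` with ``a < b`` and
    ``edge_weights[k]`` its weight. The dense adjacency matrix and weighted
    degrees are built lazily.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    edge_weights: np.ndarray
    beta: float = 1.0
    phenotype: str | None = None
    _index: dict = field(init=False, repr=False)
    _adjacency: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = tuple(tuple(e) for e in self.edges)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if len(self.edges) != len(self.edge_weights):
            raise ValueError("edges and edge_weights length mismatch")
        if np.any(self.edge_weights < 0) or np.any(self.edge_weights > 1):
            raise ValueError("edge weights must lie in [0, 1]")
        self._index = {g: i for i, g in enumerate(self.nodes)}
        for a, b in self.edges:
            if a >= b:
                raise ValueError(f"edge {(a, b)} not canonical (a < b required)")
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge {(a, b)} references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def adjacency(self) -> np.ndarray:
        """Symmetric dense weight matrix A (n x n)."""
        if self._adjacency is None:
            n = self.n_nodes
            A = np.zeros((n, n), dtype=float)
            for (a, b), w in zip(self.edges, self.edge_weights):
                i, j = self._index[a], self._index[b]
                A[i, j] = w
                A[j, i] = w
            self._adjacency = A
        return self._adjacency

    def degrees(self) -> np.ndarray:
        """Weighted degrees d_i = sum_j a_ij."""
        return self.adjacency().sum(axis=1)

    def isolated_nodes(self) -> tuple[str, ...]:
        """Nodes with no incident edge of positive weight."""
        d = self.degrees()
        return tuple(g for g, di in zip(self.nodes, d) if di == 0.0)

    def weight(self, a: str, b: str) -> float:
        i, j = self._index[a], self._index[b]
        return float(self.adjacency()[i, j])

    def edge_weight_map(self) -> dict[tuple[str, str], float]:
        return {e: float(w) for e, w in zip(self.edges, self.edge_weights)}

    def write_edge_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for (a, b), w in zip(self.edges, self.edge_weights):
                fh.write(f"{a}\t{b}\t{w:.6f}\n")


def pairwise_weight(x_i: np.ndarray, x_j: np.ndarray, beta: float = 1.0) -> float:
    """Edge weight |cor(x_i, x_j)|**beta for one phenotype's samples.

    Missing values are handled pairwise-complete; with fewer than three
    complete pairs, or a constant vector, the weight is 0 (correlation
    undefined).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"length mismatch: {x_i.shape} vs {x_j.shape}")
    if x_i.ndim != 1 or x_i.size < 3:
        raise ValueError("expression vectors must be 1-D with length >= 3")
    if beta <= 0:
        raise ValueError("beta must be positive")
    ok = ~(np.isnan(x_i) | np.isnan(x_j))
    if ok.sum() < 3:
        return 0.0
    xi, xj = x_i[ok], x_j[ok]
    xi = xi - xi.mean()
    xj = xj - xj.mean()
    denom = np.sqrt((xi**2).sum() * (xj**2).sum())
    if denom == 0.0:
        return 0.0
    r = float(np.clip((xi * xj).sum() / denom, -1.0, 1.0))
    return abs(r) ** beta


def _edge_weights_vectorized(
    X: np.ndarray, edge_idx: np.ndarray, beta: float
) -> np.ndarray:
    """Per-edge |Pearson|^beta over the columns of X for index pairs edge_idx.

    Fast path for NaN-free matrices: standardize rows once, weight is the
    absolute dot product of standardized rows. Falls back to the pairwise
    routine when missing values are present.
    """
    if np.isnan(X).any():
        return np.array(
            [pairwise_weight(X[i], X[j], beta) for i, j in edge_idx], dtype=float
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    constant = norms == 0.0
    n_const = int(constant.sum())
    if n_const:
        logger.warning("%d constant expression vectors -> incident weights set to 0", n_const)
    safe = np.where(constant, 1.0, norms)
    Z = Xc / safe[:, None]
    Z[constant] = 0.0
    r = np.einsum("ij,ij->i", Z[edge_idx[:, 0]], Z[edge_idx[:, 1]])
    return np.abs(np.clip(r, -1.0, 1.0)) ** beta


def _shared_topology(
    expr: ExpressionDataset, ppi: PpiEdgeList
) -> tuple[tuple[str, ...], list[tuple[str, str]]]:
    measured = set(expr.genes)
    nodes = tuple(sorted(ppi.genes & measured))
    node_set = set(nodes)
    edges = sorted(e for e in ppi.edges if e[0] in node_set and e[1] in node_set)
    n_dropped = len(ppi) - len(edges)
    if n_dropped:
        logger.info("dropped %d PPI edges with unmeasured endpoint", n_dropped)
    if not nodes:
        raise ValueError("no PPI gene is present in the expression matrix")
    if not edges:
        raise ValueError("no PPI edge has both endpoints measured")
    return nodes, edges


def build_network(
    expr: ExpressionDataset,
    ppi: PpiEdgeList,
    phenotype: str,
    beta: float = 1.0,
) -> WeightedNetwork:
    """Build the weighted gene-gene interaction network for one phenotype."""
    if phenotype not in expr.phenotypes:
        raise KeyError(f"phenotype {phenotype!r} not in dataset {expr.phenotypes}")
    nodes, edges = _shared_topology(expr, ppi)
    X = expr.matrix_for(phenotype)
    row = {g: expr.gene_index(g) for g in nodes}
    edge_idx = np.array([(row[a], row[b]) for a, b in edges], dtype=int)
    weights = _edge_weights_vectorized(X, edge_idx, beta)
    net = WeightedNetwork(
        nodes=nodes, edges=tuple(edges), edge_weights=weights, beta=beta, phenotype=phenotype
    )
    logger.info(
        "weighted gene-gene interaction network (%s): %d vertices and %d edges",
        phenotype,
        net.n_nodes,
        net.n_edges,
    )
    return net


def build_phenotype_pair(
    expr: ExpressionDataset, ppi: PpiEdgeList, beta: float = 1.0
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Build both phenotype networks over the identical shared topology.

    Returns the pair in sorted phenotype-label order.
    """
    pheno_a, pheno_b = expr.phenotypes
    net_a = build_network(expr, ppi, pheno_a, beta)
    net_b = build_network(expr, ppi, pheno_b, beta)
    return net_a, net_b
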