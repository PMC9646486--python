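"""Mutual k-nearest-neighbor cell graph and its random-walk transition matrix.

Mutuality caps hub degree at k and keeps the graph sparse; a cell with no
mutual neighbor is reconnected to its single nearest neighbor so every cell
keeps degree >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .lsi import LSIEmbedding

logger = logging.getLogger(__name__)

__all__ = ["CellGraph", "TransitionMatrix", "knn_search", "build_mknn_graph", "transition_matrix"]


@dataclass
class CellGraph:
    """Undirected simple graph over cells (binary adjacency, no self loops)."""

    adjacency: sparse.csr_matrix
    degree: np.ndarray
    mutual_degree: np.ndarray
    fallback_edges: list = field(default_factory=list)
    n_components: int = 1

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def to_edge_tsv(self, path) -> None:
        fb = {tuple(sorted(e)) for e in self.fallback_edges}
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        with open(path, "wt") as fh:
            fh.write("i\tj\tis_fallback\n")
            for i, j in zip(coo.row, coo.col):
                fh.write(f"{i}\t{j}\t{int((i, j) in fb)}\n")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix M with M[i, j] = A[i, j] / degree(j)."""

    M: sparse.csr_matrix

    @property
    def n_cells(self) -> int:
        return self.M.shape[0]


def knn_search(embedding: LSIEmbedding | np.ndarray, k: int = 30, chunk: int = 1024) -> np.ndarray:
    """Exact k nearest neighbors by Euclidean distance in the embedding.

    Returns an (n_cells, k) integer array, nearest first, self excluded.
    Distance ties are broken toward the lower cell index, which makes the
    result deterministic on degenerate (duplicated) inputs.
    """
    X = embedding.coords if isinstance(embedding, LSIEmbedding) else np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("embedding must be 2-D")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    out = np.empty((n, k), dtype=np.int64)
    idx = np.arange(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = cdist(X[lo:hi], X, metric="sqeuclidean")
        d2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        # lexsort: primary key distance, secondary key index (lower wins ties)
        order = np.lexsort((np.broadcast_to(idx, d2.shape), d2), axis=1)
        out[lo:hi] = order[:, :k]
    return out


def build_mknn_graph(neighbors: np.ndarray) -> CellGraph:
    """Keep an edge (i, j) only when i and j appear in each other's kNN lists.

    Any cell left without a mutual edge gains one fallback edge to its
    nearest neighbor; fallback edges are recorded and otherwise identical to
    mutual edges.  Global connectedness is checked and reported, not
    enforced.
    """
    neighbors = np.asarray(neighbors, dtype=np.int64)
    n, k = neighbors.shape
    rows = np.repeat(np.arange(n), k)
    cols = neighbors.ravel()
    directed = sparse.csr_matrix((np.ones(n * k, dtype=np.int8), (rows, cols)), shape=(n, n))
    mutual = directed.minimum(directed.T)
    mutual.eliminate_zeros()
    mutual_degree = np.asarray((mutual > 0).sum(axis=1)).ravel()

    adjacency = sparse.lil_matrix(mutual, dtype=np.int8)
    fallback_edges = []
    for i in np.nonzero(mutual_degree == 0)[0]:
        j = int(neighbors[i, 0])
        adjacency[i, j] = 1
        adjacency[j, i] = 1
        fallback_edges.append((int(i), j))
    adjacency = sparse.csr_matrix(adjacency)
    adjacency.setdiag(0)
    adjacency.eliminate_zeros()
    degree = np.asarray((adjacency > 0).sum(axis=1)).ravel()
    n_comp, _ = connected_components(adjacency, directed=False)
    if n_comp > 1:
        logger.warning("mutual-kNN graph has %d connected components; propagation stays within each", n_comp)
    return CellGraph(adjacency, degree, mutual_degree, fallback_edges, n_comp)


def transition_matrix(graph: CellGraph) -> TransitionMatrix:
    """Column-normalize the binary adjacency: each column j divided by degree(j)."""
    if graph.degree.min() < 1:
        raise ValueError("graph has an isolated node; cannot column-normalize")
    M = graph.adjacency.astype(float) @ sparse.diags(1.0 / graph.degree)
    return TransitionMatrix(sparse.csr_matrix(M))
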