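"""Latent semantic indexing of the binarized peak-by-cell matrix.

The standard scATAC-seq embedding: binarize, TF-IDF weight, truncated SVD,
keep the leading components as per-cell coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import svds

from .matrix_io import PeakCellMatrix

logger = logging.getLogger(__name__)

__all__ = ["TFIDFMatrix", "LSIEmbedding", "tfidf_transform", "lsi_embed", "load_external_embedding"]


@dataclass
class TFIDFMatrix:
    """TF-IDF weighted binary accessibility, peaks x cells, same sparsity pattern as the input."""

    weights: sparse.csr_matrix
    tf_mode: str


@dataclass
class LSIEmbedding:
    """Per-cell coordinates in LSI space (cells x d)."""

    coords: np.ndarray
    singular_values: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def to_tsv(self, path, barcodes) -> None:
        df = pd.DataFrame(self.coords, index=np.asarray(barcodes, dtype=object))
        df.index.name = "barcode"
        df.to_csv(path, sep="\t")


def tfidf_transform(matrix: PeakCellMatrix | sparse.spmatrix, tf_mode: str = "frequency") -> TFIDFMatrix:
    """Binarize the count matrix and apply TF-IDF weighting.

    The weight of peak i in cell j is ``tf_ij * log(1 + N / df_i)`` (natural
    log), where ``df_i`` is the number of cells in which peak i is open and
    N the number of cells.

    ``tf_mode``
        ``"frequency"`` (default): tf is the binary entry divided by the
        cell's total number of open peaks — weighting each cell against its
        total feature count.
        ``"binary"``: tf is the raw binary entry.
    """
    counts = matrix.counts if isinstance(matrix, PeakCellMatrix) else matrix
    if tf_mode not in ("frequency", "binary"):
        raise ValueError(f"unknown tf_mode {tf_mode!r}")
    binary = sparse.csr_matrix(counts, dtype=float, copy=True)
    binary.data = (binary.data != 0).astype(float)
    binary.eliminate_zeros()
    n_peaks, n_cells = binary.shape
    if n_cells == 0 or n_peaks == 0:
        raise ValueError("empty matrix")
    cell_totals = np.asarray(binary.sum(axis=0)).ravel()
    if np.any(cell_totals == 0):
        empties = np.nonzero(cell_totals == 0)[0]
        names = (
            list(np.asarray(matrix.barcodes)[empties[:10]])
            if isinstance(matrix, PeakCellMatrix)
            else list(empties[:10])
        )
        raise ValueError(f"{empties.size} cell(s) with zero open peaks (e.g. {names}); remove before TF-IDF")
    if tf_mode == "frequency":
        tf = binary @ sparse.diags(1.0 / cell_totals)
    else:
        tf = binary
    df_i = np.asarray(binary.sum(axis=1)).ravel()
    idf = np.zeros(n_peaks)
    present = df_i > 0
    idf[present] = np.log1p(n_cells / df_i[present])
    weights = sparse.diags(idf) @ tf
    return TFIDFMatrix(sparse.csr_matrix(weights), tf_mode)


def _canonical_signs(cell_coords: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude cell loading is positive."""
    flip = np.ones(cell_coords.shape[1])
    for j in range(cell_coords.shape[1]):
        col = cell_coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            flip[j] = -1.0
    return cell_coords * flip


def lsi_embed(tfidf: TFIDFMatrix | sparse.spmatrix, d: int = 30, rng_seed: int = 0) -> LSIEmbedding:
    """Rank-d truncated SVD of the TF-IDF matrix; returns cell-side coordinates V @ diag(sigma).

    Deterministic for a given ``rng_seed`` (the seed controls the iterative
    solver's start vector).  Component signs are canonicalized so the
    largest-magnitude loading of each component is positive; downstream
    Euclidean distances are unaffected by signs either way.
    """
    W = tfidf.weights if isinstance(tfidf, TFIDFMatrix) else sparse.csr_matrix(tfidf)
    min_dim = min(W.shape)
    if d < 2:
        raise ValueError("d must be >= 2")
    if d > min_dim:
        raise ValueError(f"d={d} exceeds min(matrix dimensions)={min_dim}")
    if d >= min_dim - 1 or min_dim <= 200:
        # iterative solvers need k < min(shape); small or near-full-rank
        # problems go through the dense path
        U, s, Vt = np.linalg.svd(np.asarray(W.todense()), full_matrices=False)
        s, Vt = s[:d], Vt[:d]
    else:
        rng = np.random.default_rng(rng_seed)
        v0 = rng.standard_normal(min(W.shape))
        U, s, Vt = svds(W, k=d, v0=v0)
        order = np.argsort(s)[::-1]
        s, Vt = s[order], Vt[order]
    coords = _canonical_signs(Vt.T * s)
    return LSIEmbedding(coords, s)


def load_external_embedding(path, barcodes) -> LSIEmbedding:
    """Adopt a precomputed embedding (e.g. batch-corrected LSI) from a TSV.

    First column holds barcodes; rows are re-ordered to the matrix barcode
    order.  Every matrix barcode must be present.
    """
    barcodes = np.asarray(barcodes, dtype=object)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [bc for bc in barcodes if bc not in df.index]
    if missing:
        raise ValueError(f"embedding file {path} missing {len(missing)} barcode(s), e.g. {missing[:5]}")
    if len(df) != len(barcodes):
        raise ValueError(
            f"embedding file {path} has {len(df)} rows but the matrix has {len(barcodes)} cells"
        )
    coords = df.loc[barcodes].to_numpy(dtype=float)
    return LSIEmbedding(coords, None)
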