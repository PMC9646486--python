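"""Readers, writers and diagnostics for peak-by-cell matrices and fine-mapped variants.

The on-disk conventions follow the dominant dialect of each format: peaks are
BED 0-based half-open intervals, variant positions are 1-based (VCF-like), the
count matrix is MatrixMarket coordinate format oriented peaks x cells, and
barcodes are one per line.  All readers transparently accept gzip-compressed
files.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "PeakCellMatrix",
    "FineMappedVariantSet",
    "read_peak_cell_matrix",
    "write_peak_cell_matrix",
    "read_finemapped_variants",
    "overlap_variants_peaks",
    "sparsity_metrics",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class PeakSet:
    """An ordered universe of genomic intervals indexed like matrix rows.

    Intervals are 0-based half-open ([start, end)).  Overlapping intervals on
    the same chromosome are permitted and are never merged.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("peak field lengths differ")
        bad = np.nonzero(self.starts >= self.ends)[0]
        if bad.size:
            raise ValueError(f"peak {bad[0]}: start >= end ({self.starts[bad[0]]} >= {self.ends[bad[0]]})")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_bed(cls, path) -> "PeakSet":
        chroms, starts, ends = [], [], []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed BED line {lineno}: need >= 3 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
                chroms.append(parts[0])
                starts.append(start)
                ends.append(end)
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends))

    def to_bed(self, path) -> None:
        with open(path, "wt") as fh:
            for c, s, e in zip(self.chroms, self.starts, self.ends):
                fh.write(f"{c}\t{s}\t{e}\n")


@dataclass
class PeakCellMatrix:
    """Sparse non-negative integer accessibility counts, peaks x cells."""

    counts: sparse.csr_matrix
    peaks: PeakSet
    barcodes: np.ndarray

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_peaks, n_cells = self.counts.shape
        if n_peaks != len(self.peaks):
            raise ValueError(
                f"dimension mismatch: matrix has {n_peaks} rows but peak set has {len(self.peaks)} intervals"
            )
        if n_cells != len(self.barcodes):
            raise ValueError(
                f"dimension mismatch: matrix has {n_cells} columns but {len(self.barcodes)} barcodes given"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts present")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class FineMappedVariantSet:
    """Fine-mapped variants for one trait with causal posterior probabilities.

    ``pos`` is 1-based.  ``pp`` lies in (0, 1].
    """

    chroms: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    pp: np.ndarray
    trait: str = "trait"

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.pp = np.asarray(self.pp, dtype=float)
        if not (len(self.chroms) == len(self.pos) == len(self.ids) == len(self.pp)):
            raise ValueError("variant field lengths differ")

    def __len__(self) -> int:
        return len(self.pos)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"chrom": self.chroms, "pos": self.pos, "id": self.ids, "pp": self.pp, "trait": self.trait}
        )
        df.to_csv(path, sep="\t", index=False)


def read_peak_cell_matrix(
    mtx_path, peaks_path, barcodes_path, *, cells_by_peaks: bool = False, validate: bool = True
) -> PeakCellMatrix:
    """Load a MatrixMarket count matrix with its BED peak file and barcode list.

    Parameters
    ----------
    cells_by_peaks
        Set when the matrix on disk is oriented cells x peaks; it is
        transposed to the internal peaks x cells orientation.
    validate
        When False, skip strict dimension/identity checks (escape hatch for
        partially processed inputs).
    """
    counts = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    if cells_by_peaks:
        counts = counts.T.tocsr()
    peaks = PeakSet.from_bed(peaks_path)
    with _open_text(barcodes_path) as fh:
        barcodes = np.array([ln.strip() for ln in fh if ln.strip()], dtype=object)
    if validate:
        if counts.shape[0] != len(peaks) or counts.shape[1] != len(barcodes):
            raise ValueError(
                "dimension mismatch: matrix is "
                f"{counts.shape[0]} x {counts.shape[1]} but {len(peaks)} peaks and "
                f"{len(barcodes)} barcodes were provided"
            )
        return PeakCellMatrix(counts, peaks, barcodes)
    obj = PeakCellMatrix.__new__(PeakCellMatrix)
    obj.counts, obj.peaks, obj.barcodes = counts, peaks, barcodes
    return obj


def write_peak_cell_matrix(matrix: PeakCellMatrix, mtx_path, peaks_path, barcodes_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(matrix.counts), field="integer")
    matrix.peaks.to_bed(peaks_path)
    with open(barcodes_path, "wt") as fh:
        for bc in matrix.barcodes:
            fh.write(f"{bc}\n")


def read_finemapped_variants(path, pp_threshold: float = 0.001, trait: str | None = None) -> FineMappedVariantSet:
    """Read tab-delimited fine-mapped variants, keeping records with PP strictly above ``pp_threshold``.

    The file carries columns ``chrom pos id pp [trait]``, with or without a
    header line.  Filtering is strict (PP == threshold is dropped); input
    order is preserved.  Duplicate variant ids raise a warning and the first
    occurrence wins.
    """
    with _open_text(path) as fh:
        first = fh.readline()
    if not first.strip():
        warnings.warn(f"{path}: empty variant file")
        return FineMappedVariantSet(np.array([]), np.array([]), np.array([]), np.array([]), trait or "trait")
    has_header = first.split("\t")[0].strip().lower() == "chrom"
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else ["chrom", "pos", "id", "pp", "trait"][: len(first.split("\t"))],
    )
    df.columns = [str(c).lower() for c in df.columns]
    for col in ("chrom", "pos", "id", "pp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    pp = df["pp"].to_numpy(dtype=float)
    if np.any(pp < 0) or np.any(pp > 1):
        bad = df.loc[(pp < 0) | (pp > 1)].iloc[0]
        raise ValueError(f"{path}: PP outside [0, 1] for variant {bad['id']} (pp={bad['pp']})")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].unique()
        warnings.warn(f"{path}: duplicate variant ids {list(dups)[:5]}; keeping first occurrence")
        df = df.loc[~df["id"].duplicated()]
        pp = df["pp"].to_numpy(dtype=float)
    keep = pp > pp_threshold
    df = df.loc[keep]
    if trait is None:
        trait = str(df["trait"].iloc[0]) if "trait" in df.columns and len(df) else "trait"
    if len(df) == 0:
        warnings.warn(f"{path}: no variants with PP > {pp_threshold}")
    return FineMappedVariantSet(
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64) if len(df) else np.array([]),
        df["id"].to_numpy(dtype=object),
        df["pp"].to_numpy(dtype=float),
        trait,
    )


def overlap_variants_peaks(variants: FineMappedVariantSet, peaks: PeakSet) -> np.ndarray:
    """Sum variant posterior probabilities into the peaks that contain them.

    A variant at 1-based position ``pos`` lands in peak [start, end) when
    ``start <= pos - 1 < end``.  A variant inside several overlapping peaks
    contributes its full PP to each.  Raises if no variant lands in any peak.
    """
    weights = np.zeros(len(peaks), dtype=float)
    trees: dict[str, IntervalTree] = {}
    for i, (c, s, e) in enumerate(zip(peaks.chroms, peaks.starts, peaks.ends)):
        trees.setdefault(c, IntervalTree()).addi(int(s), int(e), i)
    for c, p, pp in zip(variants.chroms, variants.pos, variants.pp):
        tree = trees.get(c)
        if tree is None:
            continue
        for iv in tree.at(int(p) - 1):
            weights[iv.data] += pp
    if len(variants) and weights.sum() == 0:
        raise ValueError("trait has no accessible causal variants: no variant overlaps any peak")
    return weights


def sparsity_metrics(matrix: PeakCellMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of zero entries per peak (across cells) and per cell (across peaks)."""
    if matrix.n_peaks == 0 or matrix.n_cells == 0:
        raise ValueError("empty matrix")
    nz = matrix.counts.copy()
    nz.data = (nz.data != 0).astype(np.int64)
    peak_nnz = np.asarray(nz.sum(axis=1)).ravel()
    cell_nnz = np.asarray(nz.sum(axis=0)).ravel()
    return 1.0 - peak_nnz / matrix.n_cells, 1.0 - cell_nnz / matrix.n_peaks
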