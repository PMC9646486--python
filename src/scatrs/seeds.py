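"""Per-cell trait-enrichment Z-scores and seed-cell selection.

The built-in scorer is a bias-corrected weighted-deviation scheme: variant
posterior mass on peaks is contrasted against expected accessibility from
matrix marginals, and normalized against backgrounds in which the weights
are reassigned to bias-matched peaks.  Cells whose upper-tail normal p-value
passes the filter become seed cells, capped at a fixed fraction of the
dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm
from sklearn.neighbors import NearestNeighbors

from .matrix_io import PeakCellMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TraitZScores",
    "SeedSet",
    "weighted_deviation_zscores",
    "load_external_zscores",
    "select_seed_cells",
]


@dataclass
class TraitZScores:
    """Bias-corrected enrichment Z-score per cell."""

    z: np.ndarray
    trait: str = "trait"
    method: str = "builtin"
    raw_deviation: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite Z-scores")


@dataclass
class SeedSet:
    """Boolean indicator of the seed cells that carry the initial probability mass."""

    indicator: np.ndarray
    z_threshold_used: float

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator, dtype=bool)

    @property
    def n_seeds(self) -> int:
        return int(self.indicator.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.nonzero(self.indicator)[0]


def _deviation(weights, counts, row_tot, col_tot, grand):
    # dev_c = sum_p w_p (x_pc - e_pc), e_pc = row_tot_p * col_tot_c / grand
    obs = weights @ counts
    exp = (weights @ row_tot) * col_tot / grand
    return np.asarray(obs).ravel() - exp


def _gc_from_fasta(peaks, fasta_path):
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    gc = np.zeros(len(peaks))
    for i, (c, s, e) in enumerate(zip(peaks.chroms, peaks.starts, peaks.ends)):
        seq = str(fa[str(c)][int(s):int(e)]).upper()
        gc[i] = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
    return gc


def weighted_deviation_zscores(
    matrix: PeakCellMatrix,
    peak_weights: np.ndarray,
    n_background: int = 50,
    gc: np.ndarray | None = None,
    fasta_path=None,
    n_bias_neighbors: int = 50,
    rng_seed: int = 0,
    trait: str = "trait",
) -> TraitZScores:
    """Bias-corrected weighted-deviation Z-score per cell.

    For cell c, the raw deviation is ``sum_p w_p (x_pc - e_pc)`` with
    expected counts from the matrix marginals.  Each of ``n_background``
    iterations reassigns every weighted peak's mass to a peak sampled (with
    replacement) from its nearest neighbors in standardized bias-feature
    space; the bias features are log1p mean accessibility plus GC fraction
    when a genome is available (``gc`` per-peak array or ``fasta_path``).
    The Z-score is the raw deviation standardized against the background
    mean and standard deviation.  Deterministic for a given ``rng_seed``.
    """
    peak_weights = np.asarray(peak_weights, dtype=float)
    if peak_weights.shape[0] != matrix.n_peaks:
        raise ValueError("peak_weights length does not match the number of peaks")
    if not np.any(peak_weights > 0):
        raise ValueError("all peak weights are zero; no variant mass to score")
    counts = sparse.csr_matrix(matrix.counts, dtype=float)
    row_tot = np.asarray(counts.sum(axis=1)).ravel()
    col_tot = np.asarray(counts.sum(axis=0)).ravel()
    grand = row_tot.sum()
    if grand == 0:
        raise ValueError("matrix has zero total counts")

    raw = _deviation(peak_weights, counts, row_tot, col_tot, grand)

    if gc is None and fasta_path is not None:
        gc = _gc_from_fasta(matrix.peaks, fasta_path)
    feats = [np.log1p(row_tot / matrix.n_cells)]
    if gc is not None:
        feats.append(np.asarray(gc, dtype=float))
    else:
        logger.info("no GC feature supplied; background matching uses accessibility only")
    F = np.column_stack(feats)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    F = (F - F.mean(axis=0)) / sd

    weighted = np.nonzero(peak_weights > 0)[0]
    n_nb = min(n_bias_neighbors + 1, matrix.n_peaks)
    nn = NearestNeighbors(n_neighbors=n_nb).fit(F)
    _, nbrs = nn.kneighbors(F[weighted])
    # drop self where possible so the background is a genuinely different peak
    pools = np.empty((weighted.size, n_nb - 1 if n_nb > 1 else 1), dtype=np.int64)
    for r, p in enumerate(weighted):
        row = nbrs[r][nbrs[r] != p]
        if row.size < pools.shape[1]:
            row = np.concatenate([row, nbrs[r][: pools.shape[1] - row.size]])
        pools[r] = row[: pools.shape[1]]

    rng = np.random.default_rng(rng_seed)
    bg = np.empty((n_background, matrix.n_cells))
    w_vals = peak_weights[weighted]
    for b in range(n_background):
        pick = pools[np.arange(weighted.size), rng.integers(0, pools.shape[1], size=weighted.size)]
        w_b = np.zeros(matrix.n_peaks)
        np.add.at(w_b, pick, w_vals)
        bg[b] = _deviation(w_b, counts, row_tot, col_tot, grand)

    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0, ddof=1)
    z = np.zeros(matrix.n_cells)
    ok = sd_bg > 0
    z[ok] = (raw[ok] - mean_bg[ok]) / sd_bg[ok]
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} cell(s) with zero background variance; Z set to 0")
    return TraitZScores(z, trait=trait, method="builtin", raw_deviation=raw)


def load_external_zscores(path, barcodes, trait: str = "trait") -> TraitZScores:
    """Adopt Z-scores from an external scorer (TSV: barcode, z), re-ordered to matrix barcode order."""
    barcodes = np.asarray(barcodes, dtype=object)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 0]).lower() == "barcode":
        df = df.iloc[1:]
    series = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    missing = [bc for bc in barcodes if bc not in series.index]
    if missing:
        raise ValueError(f"Z-score file {path} missing barcode(s) {missing[:5]}")
    return TraitZScores(series.loc[barcodes].to_numpy(), trait=trait, method="external")


def select_seed_cells(z: TraitZScores | np.ndarray, alpha: float = 0.05, cap_fraction: float = 0.05) -> SeedSet:
    """Seed = cells with upper-tail normal p < alpha, capped at the top ``cap_fraction`` by Z.

    The initial filter keeps cells with z above the (1 - alpha) normal
    quantile.  If more than floor(cap_fraction * N) cells pass, only the
    highest-Z cells up to that cap are kept (ties broken toward the lower
    cell index).  At least one seed is always required; zero passing cells
    is an error rather than a silent empty propagation.
    """
    zv = z.z if isinstance(z, TraitZScores) else np.asarray(z, dtype=float)
    n = zv.size
    threshold = float(norm.ppf(1.0 - alpha))
    indicator = zv > threshold
    n_init = int(indicator.sum())
    if n_init == 0:
        raise ValueError(
            f"no seed cells: max Z = {zv.max():.4f} does not exceed the z threshold {threshold:.4f} "
            f"(alpha={alpha}); consider supplying external Z-scores or raising alpha"
        )
    cap = max(1, int(np.floor(cap_fraction * n)))
    if n_init > cap:
        order = np.lexsort((np.arange(n), -zv))
        keep = order[:cap]
        indicator = np.zeros(n, dtype=bool)
        indicator[keep] = True
    return SeedSet(indicator, threshold)
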