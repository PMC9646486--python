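"""Synthetic scATAC-seq data for benchmarking the propagation pipeline.

Single cells are downsampled from bulk accessibility profiles under a
two-trial binomial model: the count of peak i in a cell of type t is
binom(2, p_i^t) with

    p_i^t = (1 - q) * r_i^t / 2 + q * n / (2 k),

where r_i^t = n * (bulk fraction of peak i in type t) is the expected
per-cell fragment count for that peak, k the number of peaks, n the target
fragments per cell and q in [0, 1] the noise level: q = 0 reproduces the
bulk composition in expectation, q = 1 scatters the n fragments uniformly
over the k peaks.  The module also fabricates bulk profiles and trait
variants from scratch so the whole pipeline can be exercised without any
external download, and scores rankings against the ground-truth labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import rankdata

from .matrix_io import FineMappedVariantSet, PeakCellMatrix, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "BulkProfile",
    "SimulationConfig",
    "SimulatedDataset",
    "synthetic_bulk_profiles",
    "synthesize_cells",
    "synthetic_variants",
    "evaluate_ranking",
]


@dataclass
class BulkProfile:
    """Bulk read counts, peaks x cell types, with the peak universe."""

    counts: np.ndarray
    peaks: PeakSet
    cell_types: list
    specific_peaks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.peaks), len(self.cell_types)):
            raise ValueError("bulk count matrix shape does not match peaks x cell types")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every cell-type column must have a positive total")


@dataclass
class SimulationConfig:
    """n: target fragments per cell; q: noise level in [0, 1]; cells_per_type per column."""

    n: int = 10000
    q: float = 0.3
    cells_per_type: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.q <= 1:
            raise ValueError("q must lie in [0, 1]")
        if self.cells_per_type < 1:
            raise ValueError("need at least one cell per type")


@dataclass
class SimulatedDataset:
    matrix: PeakCellMatrix
    labels: np.ndarray
    config: SimulationConfig
    n_clamped_peaks: int = 0


def synthetic_bulk_profiles(
    n_peaks: int = 100000,
    cell_types: tuple = ("typeA", "typeB"),
    n_specific_peaks_per_type: int = 1000,
    signal_ratio: float = 5.0,
    type_dispersion: float = 0.6,
    rng_seed: int = 0,
    peak_width: int = 500,
    peak_gap: int = 1000,
) -> BulkProfile:
    """Fabricate bulk profiles with genome-wide type differences plus specific blocks.

    Every peak gets a shared log-normal baseline; each type multiplies it by
    an independent log-normal factor with log-sd ``type_dispersion``, so
    distinct types differ across the whole peak universe the way sorted
    bulk populations do, and each type's specific block is additionally
    elevated ``signal_ratio``-fold in that type only (the landing sites for
    trait variants).  Peaks tile a single synthetic chromosome.
    Deterministic for a given ``rng_seed``.
    """
    types = list(cell_types)
    if n_specific_peaks_per_type * len(types) > n_peaks:
        raise ValueError("specific peak blocks exceed the peak universe")
    rng = np.random.default_rng(rng_seed)
    baseline = rng.lognormal(mean=3.0, sigma=0.5, size=n_peaks)
    counts = baseline[:, None] * rng.lognormal(
        mean=0.0, sigma=type_dispersion, size=(n_peaks, len(types))
    )
    specific = {}
    for t_idx, t in enumerate(types):
        lo = t_idx * n_specific_peaks_per_type
        block = np.arange(lo, lo + n_specific_peaks_per_type)
        counts[block, t_idx] *= signal_ratio
        specific[t] = block
    starts = np.arange(n_peaks, dtype=np.int64) * (peak_width + peak_gap)
    peaks = PeakSet(np.array(["chrS"] * n_peaks, dtype=object), starts, starts + peak_width)
    return BulkProfile(counts, peaks, types, specific)


def synthesize_cells(bulk: BulkProfile, config: SimulationConfig) -> SimulatedDataset:
    """Draw single cells from the bulk profile under the binomial noise model.

    Success probabilities above 1 (possible for extreme peak fractions at
    large n) are clamped; the number of clamped peaks is recorded on the
    returned dataset and logged.
    """
    k = len(bulk.peaks)
    rng = np.random.default_rng(config.rng_seed)
    blocks, labels, barcodes = [], [], []
    n_clamped = 0
    for t_idx, t in enumerate(bulk.cell_types):
        col = bulk.counts[:, t_idx]
        frac = col / col.sum()
        r = config.n * frac
        p = (1.0 - config.q) * r / 2.0 + config.q * config.n / (2.0 * k)
        over = p > 1.0
        n_clamped += int(over.sum())
        p = np.clip(p, 0.0, 1.0)
        draws = rng.binomial(2, p[:, None], size=(k, config.cells_per_type)).astype(np.int8)
        blocks.append(sparse.csr_matrix(draws))
        labels.extend([t] * config.cells_per_type)
        barcodes.extend(f"{t}_{i:05d}" for i in range(config.cells_per_type))
    if n_clamped:
        logger.info("clamped p > 1 on %d peak/type combinations", n_clamped)
    counts = sparse.hstack(blocks, format="csr")
    matrix = PeakCellMatrix(counts, bulk.peaks, np.array(barcodes, dtype=object))
    return SimulatedDataset(matrix, np.array(labels, dtype=object), config, n_clamped)


def synthetic_variants(
    bulk: BulkProfile,
    target_type: str,
    n_variants: int = 50,
    target_fraction: float = 0.8,
    pp_concentration: float = 2.0,
    rng_seed: int = 0,
) -> FineMappedVariantSet:
    """Place fine-mapped variants preferentially inside the target type's specific peaks.

    ``target_fraction`` of the variants land uniformly inside
    target-specific peaks, the rest uniformly inside the remaining peaks.
    Posterior probabilities are Beta(pp_concentration, 1) draws — right-
    skewed toward confident assignments, as retained fine-mapped variants
    are.  Deterministic for a given ``rng_seed``.
    """
    if target_type not in bulk.specific_peaks or len(bulk.specific_peaks[target_type]) == 0:
        raise ValueError(f"bulk profile has no specific peaks recorded for type {target_type!r}")
    rng = np.random.default_rng(rng_seed)
    target_block = np.asarray(bulk.specific_peaks[target_type])
    other = np.setdiff1d(np.arange(len(bulk.peaks)), target_block)
    n_target = int(round(target_fraction * n_variants))
    peak_choice = np.concatenate(
        [
            rng.choice(target_block, size=n_target, replace=True),
            rng.choice(other, size=n_variants - n_target, replace=True) if n_variants > n_target else [],
        ]
    ).astype(np.int64)
    starts = bulk.peaks.starts[peak_choice]
    ends = bulk.peaks.ends[peak_choice]
    pos0 = rng.integers(starts, ends)  # 0-based inside [start, end)
    pp = rng.beta(pp_concentration, 1.0, size=n_variants)
    pp = np.clip(pp, 1e-6, 1.0)
    return FineMappedVariantSet(
        bulk.peaks.chroms[peak_choice],
        pos0 + 1,
        np.array([f"rs_sim_{i}" for i in range(n_variants)], dtype=object),
        pp,
        trait="synthetic_trait",
    )


def evaluate_ranking(scores: np.ndarray, labels: np.ndarray, positive_type: str) -> dict:
    """Score a per-cell ranking against ground-truth labels.

    Cells are ranked by score descending and the top-P cells are called
    positive, where P is the true positive count; accuracy, TPR and FPR are
    computed at that cut.  auROC is the Mann-Whitney rank statistic with
    ties averaged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_type
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to evaluate a ranking")
    ranks = rankdata(scores)  # average ranks for ties
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.lexsort((np.arange(scores.size), -scores))
    predicted = np.zeros(scores.size, dtype=bool)
    predicted[order[:n_pos]] = True
    tp = int((predicted & y).sum())
    fp = n_pos - tp
    accuracy = (tp + (n_neg - fp)) / scores.size
    return {
        "accuracy": accuracy,
        "auroc": float(auroc),
        "tpr": tp / n_pos,
        "fpr": fp / n_neg,
    }
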