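"""High-level orchestration: matrix + variants in, per-cell report out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import CellGraph, TransitionMatrix, build_mknn_graph, knn_search, transition_matrix
from .lsi import LSIEmbedding, lsi_embed, tfidf_transform
from .matrix_io import FineMappedVariantSet, PeakCellMatrix, overlap_variants_peaks
from .permutation import PermutationResult, permutation_test
from .propagation import PropagationConfig, compute_trs, initial_distribution, random_walk_restart
from .seeds import TraitZScores, select_seed_cells, weighted_deviation_zscores

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one full run produces, with a tabular per-cell view."""

    z: TraitZScores
    seed_indicator: np.ndarray
    embedding: LSIEmbedding
    graph: CellGraph
    M: TransitionMatrix
    np_score: np.ndarray
    trs: np.ndarray
    scale_factor: float
    iterations: int
    converged: bool
    permutation: PermutationResult | None = None

    def to_frame(self, barcodes) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "barcode": np.asarray(barcodes, dtype=object),
                "z": self.z.z,
                "is_seed": self.seed_indicator.astype(int),
                "np": self.np_score,
                "trs": self.trs,
            }
        )
        if self.permutation is not None:
            df["p"] = self.permutation.pvalues
            df["state"] = self.permutation.state
        return df


def run_pipeline(
    matrix: PeakCellMatrix,
    variants: FineMappedVariantSet | None = None,
    *,
    z: TraitZScores | None = None,
    embedding: LSIEmbedding | None = None,
    d: int = 30,
    tf_mode: str = "frequency",
    k: int = 30,
    seed_alpha: float = 0.05,
    cap_fraction: float = 0.05,
    n_background: int = 50,
    gamma: float = 0.05,
    tol: float = 1e-5,
    max_iter: int = 1000,
    norm: str = "l1",
    permute_B: int = 0,
    perm_alpha: float = 0.05,
    rng_seed: int = 0,
) -> PipelineResult:
    """Run enrichment scoring, graph construction, propagation, TRS and (optionally) the permutation test.

    Either ``variants`` (scored with the built-in weighted-deviation scheme)
    or a precomputed ``z`` must be given; a precomputed ``embedding``
    replaces the internal TF-IDF/LSI step.  ``permute_B`` > 0 appends the
    degree-matched permutation test with that many permutations.
    """
    if z is None:
        if variants is None:
            raise ValueError("either variants or precomputed z-scores are required")
        weights = overlap_variants_peaks(variants, matrix.peaks)
        z = weighted_deviation_zscores(
            matrix, weights, n_background=n_background, rng_seed=rng_seed, trait=variants.trait
        )
    seed_set = select_seed_cells(z, alpha=seed_alpha, cap_fraction=cap_fraction)
    logger.info("selected %d seed cells (z > %.4f)", seed_set.n_seeds, seed_set.z_threshold_used)

    if embedding is None:
        embedding = lsi_embed(tfidf_transform(matrix, tf_mode=tf_mode), d=d, rng_seed=rng_seed)
    graph = build_mknn_graph(knn_search(embedding, k=k))
    M = transition_matrix(graph)

    config = PropagationConfig(gamma=gamma, tol=tol, max_iter=max_iter, norm=norm)
    scores = random_walk_restart(M, initial_distribution(seed_set), config)
    logger.info("propagation converged=%s after %d iterations", scores.converged, scores.iterations)
    trs = compute_trs(scores, z)

    perm = None
    if permute_B > 0:
        perm = permutation_test(
            M, graph, seed_set, scores.np_score, config, B=permute_B, alpha=perm_alpha, rng_seed=rng_seed
        )
        logger.info("permutation test: %.2f%% of cells enriched", 100.0 * np.mean(perm.state == "enriched"))
    return PipelineResult(
        z,
        seed_set.indicator,
        embedding,
        graph,
        M,
        scores.np_score,
        trs.trs,
        trs.scale_factor,
        scores.iterations,
        scores.converged,
        perm,
    )
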