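"""Degree-matched permutation null for network-propagation scores.

Permuted seed sets preserve the degree multiset of the real seeds so the
null carries the same graph-topology confounding; each permutation reruns
the restart walk and the per-cell empirical p-value follows the add-one
rule p = (1 + #{permuted >= real}) / (1 + B), so p can never reach 0 and
ties count against the real score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .graph import CellGraph, TransitionMatrix
from .propagation import PropagationConfig, initial_distribution, random_walk_restart
from .seeds import SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "degree_matched_seed_sample",
    "permutation_null",
    "empirical_pvalues",
    "classify_cells",
    "permutation_test",
]

ENRICHED = "enriched"
DEPLETED = "depleted"


@dataclass
class PermutationResult:
    B: int
    exceed_counts: np.ndarray
    pvalues: np.ndarray
    state: np.ndarray
    alpha: float = 0.05


def degree_matched_seed_sample(
    graph: CellGraph, seed_set: SeedSet | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a seed set of equal size whose degree multiset matches the real seeds.

    Within each degree class, candidates are drawn without replacement from
    all cells of that degree (real seeds included — excluding them would
    distort the null when seeds dominate a class).  A class with too few
    distinct candidates borrows from the nearest degree values (+-1, +-2,
    ...) with a warning; if the graph is too small or degenerate for any
    matching, sampling falls back to size-matched unconstrained draws.
    """
    indicator = seed_set.indicator if isinstance(seed_set, SeedSet) else np.asarray(seed_set, dtype=bool)
    seed_idx = np.nonzero(indicator)[0]
    if seed_idx.size == 0:
        raise ValueError("empty seed set")
    degree = graph.degree
    n = degree.size
    if n < 2 * seed_idx.size and len(np.unique(degree)) > 1:
        warnings.warn("too few cells for degree matching; falling back to unconstrained size-matched sampling")
        return rng.choice(n, size=seed_idx.size, replace=False)

    available = np.ones(n, dtype=bool)
    chosen: list[int] = []
    seed_degrees, needs = np.unique(degree[seed_idx], return_counts=True)
    for d, need in zip(seed_degrees, needs):
        pool = np.nonzero((degree == d) & available)[0]
        width = 0
        while pool.size < need:
            width += 1
            if width > int(degree.max()) + 1:
                break
            pool = np.nonzero((np.abs(degree - d) <= width) & available)[0]
        if width > 0 and pool.size >= need:
            logger.debug("degree class %d short; expanded to +-%d", d, width)
        if pool.size < need:
            warnings.warn("degree matching infeasible; falling back to unconstrained size-matched sampling")
            return rng.choice(n, size=seed_idx.size, replace=False)
        pick = rng.choice(pool, size=need, replace=False)
        available[pick] = False
        chosen.extend(int(i) for i in pick)
    return np.array(sorted(chosen), dtype=np.int64)


def permutation_null(
    M: TransitionMatrix,
    graph: CellGraph,
    seed_set: SeedSet,
    config: PropagationConfig | None = None,
    B: int = 1000,
    rng_seed: int = 0,
) -> np.ndarray:
    """B restart walks from independent degree-matched seed draws; returns a (B, n_cells) score matrix.

    Each permutation derives its generator from (rng_seed, b) so draws are
    independent yet individually reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or PropagationConfig()
    n = graph.n_cells
    out = np.empty((B, n))
    for b in range(B):
        rng = np.random.default_rng([rng_seed, b])
        perm_idx = degree_matched_seed_sample(graph, seed_set, rng)
        ind = np.zeros(n, dtype=bool)
        ind[perm_idx] = True
        v0 = initial_distribution(ind)
        out[b] = random_walk_restart(M, v0, config).np_score
    return out


def empirical_pvalues(real_np: np.ndarray, permuted_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Add-one empirical p per cell: (1 + #{b : real <= permuted_b}) / (1 + B)."""
    real_np = np.asarray(real_np, dtype=float)
    permuted_scores = np.atleast_2d(np.asarray(permuted_scores, dtype=float))
    if permuted_scores.shape[1] != real_np.size:
        raise ValueError("permuted score matrix width does not match the number of cells")
    B = permuted_scores.shape[0]
    exceed = (permuted_scores >= real_np[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + B), exceed


def classify_cells(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Enriched iff p < alpha (strict), otherwise depleted."""
    pvalues = np.asarray(pvalues, dtype=float)
    return np.where(pvalues < alpha, ENRICHED, DEPLETED)


def permutation_test(
    M: TransitionMatrix,
    graph: CellGraph,
    seed_set: SeedSet,
    real_np: np.ndarray,
    config: PropagationConfig | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> PermutationResult:
    """Full degree-matched permutation test: null scores, empirical p, enrichment state."""
    permuted = permutation_null(M, graph, seed_set, config, B=B, rng_seed=rng_seed)
    pvals, exceed = empirical_pvalues(real_np, permuted)
    return PermutationResult(B, exceed, pvals, classify_cells(pvals, alpha), alpha)
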