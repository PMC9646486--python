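"""Random walk with restart over the cell graph and the trait relevance score.

Probability mass starts uniformly on the seed cells and diffuses along the
column-stochastic transition matrix, restarting to the seeds with
probability gamma each step:

    v_{s+1} = (1 - gamma) * M @ v_s + gamma * v_0

The update is a contraction with Lipschitz constant (1 - gamma) in L1, so it
converges geometrically to the unique fixed point
gamma * (I - (1 - gamma) M)^{-1} v_0, a probability vector.  The stationary
vector is the network-propagation (NP) score; the trait relevance score
(TRS) is the NP score clipped at a high quantile, min-max scaled to [0, 1]
and multiplied by the mean enrichment Z of the top cells so magnitudes stay
comparable across datasets of different size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .graph import TransitionMatrix
from .seeds import SeedSet, TraitZScores

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "PropagationScores",
    "TRSVector",
    "initial_distribution",
    "random_walk_restart",
    "solve_stationary_exact",
    "compute_trs",
]

_DENSE_SOLVE_GUARD = 5000


@dataclass
class PropagationConfig:
    """Random-walk parameters.

    gamma : restart probability in (0, 1); 0.05 by default.
    tol : convergence threshold on the norm of successive differences (1e-5).
    max_iter : iteration cap; convergence is guaranteed mathematically, the
        cap only catches precision pathologies.
    norm : "l1" (default, natural for probability vectors) or "linf".
    """

    gamma: float = 0.05
    tol: float = 1e-5
    max_iter: int = 1000
    norm: str = "l1"

    def __post_init__(self):
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.norm not in ("l1", "linf"):
            raise ValueError("norm must be 'l1' or 'linf'")


@dataclass
class PropagationScores:
    """Stationary distribution of the restart walk (sums to 1)."""

    np_score: np.ndarray
    iterations: int
    converged: bool


@dataclass
class TRSVector:
    """Per-cell trait relevance score with the normalization constants used."""

    trs: np.ndarray
    scale_factor: float
    ceiling_value: float


def initial_distribution(seed_set: SeedSet | np.ndarray, n_cells: int | None = None) -> np.ndarray:
    """Uniform probability over the seed cells, zero elsewhere."""
    if isinstance(seed_set, SeedSet):
        indicator = seed_set.indicator
    else:
        indicator = np.asarray(seed_set, dtype=bool)
    if n_cells is not None and indicator.size != n_cells:
        raise ValueError("seed indicator length does not match n_cells")
    n_seeds = int(indicator.sum())
    if n_seeds == 0:
        raise ValueError("empty seed set")
    v0 = np.zeros(indicator.size)
    v0[indicator] = 1.0 / n_seeds
    return v0


def _check_stochastic(M: sparse.spmatrix) -> None:
    colsums = np.asarray(M.sum(axis=0)).ravel()
    if not np.allclose(colsums, 1.0, atol=1e-10):
        raise ValueError("transition matrix is not column-stochastic")


def random_walk_restart(
    M: TransitionMatrix | sparse.spmatrix, v0: np.ndarray, config: PropagationConfig | None = None
) -> PropagationScores:
    """Iterate v <- (1 - gamma) M v + gamma v0 until the configured norm of the step falls below tol."""
    config = config or PropagationConfig()
    Ms = M.M if isinstance(M, TransitionMatrix) else sparse.csr_matrix(M)
    _check_stochastic(Ms)
    v0 = np.asarray(v0, dtype=float)
    if not np.isclose(v0.sum(), 1.0, atol=1e-8) or v0.min() < 0:
        raise ValueError("v0 must be a probability vector")
    v = v0.copy()
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        v_next = (1.0 - config.gamma) * (Ms @ v) + config.gamma * v0
        diff = v_next - v
        step = np.abs(diff).sum() if config.norm == "l1" else np.abs(diff).max()
        v = v_next
        if step < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"random walk did not converge within {config.max_iter} iterations")
    return PropagationScores(v, it, converged)


def solve_stationary_exact(
    M: TransitionMatrix | sparse.spmatrix, v0: np.ndarray, gamma: float = 0.05
) -> np.ndarray:
    """Direct fixed point gamma * (I - (1 - gamma) M)^{-1} v0 via a dense solve.

    Guarded to small graphs; it exists as the exact counterpart of the
    iterative walk (and as the test oracle for it).
    """
    Ms = M.M if isinstance(M, TransitionMatrix) else sparse.csr_matrix(M)
    n = Ms.shape[0]
    if n > _DENSE_SOLVE_GUARD:
        raise ValueError(f"dense solve guarded at {_DENSE_SOLVE_GUARD} cells; use random_walk_restart")
    _check_stochastic(Ms)
    A = np.eye(n) - (1.0 - gamma) * np.asarray(Ms.todense())
    v = gamma * np.linalg.solve(A, np.asarray(v0, dtype=float))
    return v


def compute_trs(
    scores: PropagationScores | np.ndarray,
    z: TraitZScores | np.ndarray,
    ceiling_quantile: float = 0.99,
    top_fraction: float = 0.01,
) -> TRSVector:
    """Clip NP scores at the ceiling quantile, min-max scale to [0, 1], multiply by the top-Z mean.

    The ceiling (99th percentile by default, linear-interpolation quantile)
    levels the few extreme cells; the scale factor is the mean Z of the
    ceil(top_fraction * N) highest-Z cells, anchoring the TRS to the
    enrichment analysis.  A negative scale factor is passed through with a
    warning — clamping would silently misrank cells.
    """
    np_score = scores.np_score if isinstance(scores, PropagationScores) else np.asarray(scores, dtype=float)
    zv = z.z if isinstance(z, TraitZScores) else np.asarray(z, dtype=float)
    n = np_score.size
    if zv.size != n:
        raise ValueError("NP score and Z vectors differ in length")
    if n < 2:
        raise ValueError("need at least two cells")
    ceiling = float(np.quantile(np_score, ceiling_quantile))
    clipped = np.minimum(np_score, ceiling)
    m_top = int(np.ceil(top_fraction * n))
    top_idx = np.lexsort((np.arange(n), -zv))[:m_top]
    scale = float(zv[top_idx].mean())
    if scale < 0:
        warnings.warn("scale factor (mean top-Z) is negative; TRS returned with its sign as-is")
    span = clipped.max() - clipped.min()
    if span == 0:
        warnings.warn("constant NP score vector after clipping; TRS is all zeros")
        return TRSVector(np.zeros(n), scale, ceiling)
    scaled = (clipped - clipped.min()) / span
    return TRSVector(scaled * scale, scale, ceiling)
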