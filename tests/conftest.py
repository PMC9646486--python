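import numpy as np
import pytest
from scipy import sparse

import scatrs
from scatrs.matrix_io import PeakCellMatrix, PeakSet


def make_peaks(n, chrom="chr1", width=500, gap=1000):
    starts = np.arange(n, dtype=np.int64) * (width + gap)
    return PeakSet(np.array([chrom] * n, dtype=object), starts, starts + width)


def random_matrix(n_peaks, n_cells, density=0.3, seed=0, max_count=5):
    rng = np.random.default_rng(seed)
    mat = sparse.random(
        n_peaks, n_cells, density=density, random_state=rng,
        data_rvs=lambda k: rng.integers(1, max_count + 1, size=k),
    )
    counts = sparse.csr_matrix(mat, dtype=np.int64)
    # TF-IDF needs every cell open somewhere
    for j in np.nonzero(np.asarray((counts != 0).sum(axis=0)).ravel() == 0)[0]:
        counts[j % n_peaks, j] = 1
    barcodes = np.array([f"BC{j:04d}" for j in range(n_cells)], dtype=object)
    return PeakCellMatrix(sparse.csr_matrix(counts), make_peaks(n_peaks), barcodes)


@pytest.fixture
def small_matrix():
    return random_matrix(30, 10, seed=42)


# ---- the standard synthetic benchmark fixture: two cell types, 300 + 300
# cells, 10,000 fragments per cell against a 100k-peak universe, noise 0.3 ----

STANDARD = dict(n_peaks=100_000, n_specific=1000, signal_ratio=5.0, n=10_000, q=0.3,
                cells_per_type=300, n_variants=50, target="typeA")


def simulate_standard(seed, q=None, cells_per_type=None):
    """One full synthetic dataset + variants under the standard conditions."""
    bulk = scatrs.synthetic_bulk_profiles(
        n_peaks=STANDARD["n_peaks"], cell_types=("typeA", "typeB"),
        n_specific_peaks_per_type=STANDARD["n_specific"],
        signal_ratio=STANDARD["signal_ratio"], rng_seed=seed,
    )
    config = scatrs.SimulationConfig(
        n=STANDARD["n"], q=STANDARD["q"] if q is None else q,
        cells_per_type=cells_per_type or STANDARD["cells_per_type"], rng_seed=seed,
    )
    dataset = scatrs.synthesize_cells(bulk, config)
    variants = scatrs.synthetic_variants(bulk, STANDARD["target"], n_variants=STANDARD["n_variants"],
                                         rng_seed=seed)
    return bulk, dataset, variants


@pytest.fixture(scope="session")
def standard_run():
    """Shared full pipeline run on the standard fixture (seed 11)."""
    bulk, dataset, variants = simulate_standard(seed=11)
    result = scatrs.run_pipeline(dataset.matrix, variants, rng_seed=11)
    return dict(bulk=bulk, dataset=dataset, variants=variants, result=result)


def random_mknn_transition(n, k=10, d=5, seed=0):
    """A random mutual-kNN graph and its transition matrix from Gaussian points."""
    rng = np.random.default_rng(seed)
    emb = rng.standard_normal((n, d))
    graph = scatrs.build_mknn_graph(scatrs.knn_search(emb, k=k))
    return graph, scatrs.transition_matrix(graph)
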