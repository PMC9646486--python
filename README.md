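# scatrs

Per-cell **trait relevance scoring** for scATAC-seq via seeded network
propagation of fine-mapped GWAS variants.

## The problem

GWAS fine-mapping assigns each variant a posterior probability (PP) of being
causal for a trait. Overlaying those variants on single-cell chromatin
accessibility should reveal *which cells* the trait acts through — but
scATAC-seq is extremely sparse (most peaks are unobserved in any given
cell), so per-cell co-localization statistics are informative only for a
handful of cells. `scatrs` overcomes the sparsity by diffusing the signal of
the most confidently trait-enriched cells over a cell-to-cell similarity
graph, producing a trait relevance score (TRS) for every cell.

## The method

1. **Enrichment Z-scores.** For each cell *c*, a bias-corrected weighted
   deviation score contrasts observed accessibility in variant-bearing peaks
   against the expectation from the matrix marginals,
   `dev_c = Σ_p w_p (x_pc − e_pc)`, where `w_p` is the summed PP of variants
   in peak *p*. The raw deviation is standardized against backgrounds in
   which the weights are reassigned to accessibility-matched (optionally
   GC-matched) peaks, yielding a Z-score per cell.
2. **Seed cells.** Cells with upper-tail normal *p* < 0.05 are seeds, capped
   at the top 5 % of cells by Z.
3. **Cell graph.** The binarized matrix is TF-IDF weighted
   (`w_ij = tf_ij · log(1 + N/df_i)`), embedded with a rank-30 truncated SVD
   (LSI), and cells are joined in a **mutual** k-nearest-neighbor graph
   (k = 30): an edge exists only when two cells appear in each other's kNN
   lists, which caps hub degree and keeps the graph sparse.
4. **Random walk with restart.** With column-stochastic transition matrix
   `M` and the uniform seed distribution `v₀`, iterate
   `v ← (1 − γ) M v + γ v₀` (γ = 0.05) until the L1 step falls below 1e-5.
   The stationary distribution is the network-propagation (NP) score.
5. **TRS.** NP scores are clipped at their 99th percentile, min-max scaled
   to [0, 1], and multiplied by the mean Z of the top-1 % cells so scores
   stay comparable across datasets.
6. **Permutation test.** B = 1,000 re-propagations from degree-matched
   random seed sets give each cell an empirical
   `p = (1 + #{permuted ≥ real}) / (1 + B)`; cells with *p* < 0.05 are
   called trait-enriched.

A binomial simulator (`binom(2, p_i^t)` with
`p_i^t = (1 − q) r_i^t / 2 + q·n / 2k`) downsamples single cells from bulk
accessibility profiles, with ground-truth labels for benchmarking.

## Worked example

```python
import numpy as np
import scatrs

# Fully synthetic benchmark: two cell types, 500 cells each, 10,000
# fragments per cell against a 100k-peak universe, noise q = 0.3, with 50
# fine-mapped variants concentrated in the "mono" type's specific peaks.
bulk = scatrs.synthetic_bulk_profiles(
    n_peaks=100_000, cell_types=("mono", "nk"),
    n_specific_peaks_per_type=1000, signal_ratio=5.0, rng_seed=1,
)
dataset = scatrs.synthesize_cells(
    bulk, scatrs.SimulationConfig(n=10_000, q=0.3, cells_per_type=500, rng_seed=1)
)
variants = scatrs.synthetic_variants(bulk, "mono", n_variants=50, rng_seed=1)

result = scatrs.run_pipeline(dataset.matrix, variants, permute_B=1000, rng_seed=1)

before = scatrs.evaluate_ranking(result.z.z, dataset.labels, "mono")
after = scatrs.evaluate_ranking(result.trs, dataset.labels, "mono")
print(f"seed cells:            {int(result.seed_indicator.sum())} / {dataset.matrix.n_cells}")
print(f"accuracy (Z only):     {before['accuracy']:.3f}")
print(f"accuracy (TRS):        {after['accuracy']:.3f}")
```

Output:

```
seed cells:            50 / 1000
accuracy (Z only):     0.988
accuracy (TRS):        1.000
```

The Z-score ranking alone already separates the two types well on this
fixture but misclassifies a tail of sparse cells; propagation recovers them
(accuracy 0.988 → 1.000). Adding `permute_B=1000` runs the degree-matched
permutation test; on this fixture 30.9 % of cells are called enriched and
every one of them is a true "mono" cell.

## Command-line interface

Staged commands with plain-TSV handoffs, so externally computed Z-scores or
a batch-corrected embedding can replace any internal stage:

```bash
scatrs simulate --outdir sim/ --seed 1
scatrs score     --mtx sim/matrix.mtx --peaks sim/peaks.bed --barcodes sim/barcodes.txt \
                 --variants sim/variants.tsv --outdir out/
scatrs propagate --mtx sim/matrix.mtx --peaks sim/peaks.bed --barcodes sim/barcodes.txt \
                 --scores out/scores.tsv --outdir out/
scatrs permute   --mtx sim/matrix.mtx --peaks sim/peaks.bed --barcodes sim/barcodes.txt \
                 --scores out/scores.tsv --outdir out/ -B 1000
# or everything at once:
scatrs run --mtx sim/matrix.mtx --peaks sim/peaks.bed --barcodes sim/barcodes.txt \
           --variants sim/variants.tsv --outdir out/ -B 1000
```

Inputs: MatrixMarket counts (peaks × cells; `--cells-by-peaks` to
transpose), BED peaks (0-based half-open), one-barcode-per-line text, and
variants as TSV `chrom pos id pp [trait]` (1-based positions; records with
PP ≤ 0.001 are dropped). All readers accept gzip.

## Layout

| module | contents |
| --- | --- |
| `scatrs.matrix_io` | MTX/BED/barcode/variant readers and writers, variant–peak overlap, sparsity diagnostics |
| `scatrs.lsi` | TF-IDF weighting, truncated-SVD embedding, external-embedding import |
| `scatrs.graph` | exact kNN search, mutual-kNN graph, column-stochastic transition matrix |
| `scatrs.seeds` | bias-corrected weighted-deviation Z-scores, seed selection, external-Z import |
| `scatrs.propagation` | restart walk, exact stationary solve, TRS normalization |
| `scatrs.permutation` | degree-matched seed sampling, permutation null, empirical p |
| `scatrs.simulate` | synthetic bulk profiles, binomial single-cell simulator, ranking metrics |
| `scatrs.pipeline` / `scatrs.cli` | orchestration and the `scatrs` command |

See `docs/methods.md` for the model, parameter defaults, and the numerical
and design choices.
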