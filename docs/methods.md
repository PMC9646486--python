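# Methods

This note documents the model implemented by `scatrs`, its parameter
defaults, the numerical choices, what the synthetic benchmark does and does
not establish, and known limitations.

## Model

### Enrichment Z-scores (seed scoring)

For a peaks × cells count matrix `X` and per-peak variant weights
`w_p = Σ PP` over the fine-mapped variants falling in peak `p` (1-based
variant positions tested against 0-based half-open peaks; a variant inside
several overlapping peaks contributes its full PP to each), the raw
deviation of cell `c` is

```
dev_c = Σ_p w_p (x_pc − e_pc),    e_pc = row_total_p · col_total_c / grand_total
```

i.e. observed accessibility at variant peaks minus the expectation under
independence of peaks and cells. Because deviations are confounded by
technical covariates (mean accessibility, GC content, PCR amplification),
the score is standardized against `n_background = 50` backgrounds in which
each weighted peak's mass is reassigned to a peak sampled with replacement
from its 50 nearest neighbors in standardized bias-feature space. The bias
features are log1p mean accessibility and, when a genome FASTA or a
per-peak GC vector is supplied, GC fraction; without a genome the matching
uses accessibility alone (logged). The Z-score is
`z_c = (dev_c − mean_bg) / sd_bg` with the sample standard deviation; cells
with zero background variance get z = 0 and a warning.

This scorer is an independently specified weighted-deviation scheme in the
chromVAR family. Numerical parity with any particular external
implementation is not promised; externally computed Z-scores can be
supplied verbatim (`load_external_zscores`, `--scores`) and flow through
the rest of the pipeline unchanged.

### Seed cells

Cells with upper-tail normal p < `alpha = 0.05` (z > Φ⁻¹(0.95) ≈ 1.6449)
are initial seeds. If more than `floor(cap_fraction · N)` cells pass
(`cap_fraction = 0.05`), only the highest-Z cells up to the cap are kept.
Unstated details fixed here for determinism: the cap uses `floor` (clamped
to ≥ 1), ties at the cutoff break toward the lower cell index, and the
one-tailed test is the upper tail with a plain (uncorrected) normal.

### Embedding and graph

The counts are binarized and TF-IDF weighted:
`w_ij = tf_ij · log(1 + N / df_i)` with the natural logarithm (the
convention of the standard LSI implementations; the base is a choice, not a
given). Two readings of the term frequency are exposed: `frequency`
(default) divides the binary entry by the cell's total open-peak count —
weighting each cell against its total number of features — while `binary`
uses the raw binary entry. A rank-`d = 30` truncated SVD of the TF-IDF
matrix gives cell coordinates `V·diag(σ)`. The iterative solver is seeded
(deterministic) and component signs are canonicalized (largest-magnitude
loading positive); small or near-full-rank problems use a dense SVD. No
depth-correlated component is dropped by default. Precomputed embeddings
(e.g. batch-corrected LSI) can be loaded from TSV and replace this stage.

Exact k-nearest neighbors (`k = 30`, Euclidean distance, ties broken toward
the lower cell index) feed a **mutual** kNN graph: edge (i, j) exists iff
each cell is in the other's list. A cell with no mutual edge is connected
to its single nearest neighbor (a recorded "fallback" edge), guaranteeing
minimum degree 1 — not global connectivity, which is checked and logged but
not enforced; propagation remains well-defined on a disconnected graph
(mass stays within seeded components). kNN search is brute-force (exact);
datasets of the intended scale fit comfortably in memory.

### Random walk with restart

With binary adjacency `A`, the transition matrix is the column
normalization `M_ij = A_ij / degree(j)`. From the uniform seed distribution
`v₀` the walk iterates

```
v ← (1 − γ) M v + γ v₀,     γ = 0.05
```

starting at `v = v₀`, stopping when the step norm falls below
`tol = 1e-5`. The update uses column vectors and a column-stochastic `M`,
which conserves total mass (every iterate sums to 1) and makes the fixed
point `γ (I − (1 − γ) M)⁻¹ v₀` a probability vector. The convergence norm
is L1 by default (natural for probability vectors; L∞ available). The map
is a contraction with constant (1 − γ), so convergence is geometric; a
`max_iter = 1000` guard catches only precision pathologies.
`solve_stationary_exact` computes the fixed point directly (dense solve,
guarded at 5,000 cells) and serves as the independent cross-check of the
iterative path.

### Trait relevance score

NP scores are clipped at their 99th percentile (linear-interpolation
quantile; values equal to the ceiling are unchanged), min-max scaled to
[0, 1], and multiplied by the mean Z of the `ceil(0.01 · N)` highest-Z
cells. The scale factor anchors the TRS to the enrichment analysis and
makes scores comparable across datasets of different size (raw NP scores
scale like 1/N). A negative scale factor (all-negative top Z) is passed
through with a warning rather than clamped — silently flipping the sign
would misrank cells.

### Permutation test

Per-cell significance uses NP scores (not TRS: NP sums to 1 regardless of
seed choice, so scores from different seed sets are directly comparable).
Each of `B = 1000` permutations redraws a seed set of identical size whose
degree multiset matches the real seeds — within each degree class, sampled
without replacement from all cells of that degree. Real seeds are eligible
candidates (excluding them would distort the null when seeds dominate a
degree class). A degree class with too few candidates borrows from the
nearest degree values (±1, ±2, …) with a warning; if matching is infeasible
the sampler falls back to size-matched unconstrained draws, loudly. Degree
means total degree, fallback edges included — the quantity that shapes
propagation. The empirical p is the add-one formula

```
p_c = (1 + #{b : NP_c ≤ NP_c^(b)}) / (1 + B)
```

so p ∈ [1/(B+1), 1] and ties count against the real score (the indicator's
≤ wins over the looser prose reading "greater than"). Cells with p < 0.05
are "enriched", others "depleted"; no multiple-testing correction is
applied — the per-cell empirical p is the method's definition, and FDR
control across cells is left to the user's discretion. Each permutation's
generator is derived from (seed, b), so the B draws are independent and
individually reproducible.

## Synthetic benchmark

`synthesize_cells` draws each single-cell count as `binom(2, p_i^t)` with

```
p_i^t = (1 − q) r_i^t / 2 + q n / (2k)
```

where `r_i^t = n · f_i^t` is the expected per-cell fragment count of peak
`i` in type `t` (`f_i^t` the bulk column fraction), `k` the number of
peaks, `n` the target fragments per cell and `q ∈ [0, 1]` the noise level.
This reading of `r` (expected count, i.e. n × bulk fraction) is forced by
the limits: at q = 0 the expected count equals `r_i`, and at q = 1 the
formula collapses to a uniform scatter of n fragments over k peaks —
`p = n/(2k)` — which only balances dimensionally under this normalization.
Probabilities above 1 (possible for extreme peak fractions at large n) are
clamped and counted.

`synthetic_bulk_profiles` fabricates the bulk inputs so the whole pipeline
runs self-contained: a shared log-normal baseline per peak, an independent
per-type log-normal factor (log-sd `type_dispersion = 0.6`) giving
genome-wide between-type differences — as distinct sorted populations show
— and disjoint type-specific blocks elevated `signal_ratio = 5`-fold that
serve as landing sites for `synthetic_variants` (default 50 variants, 80 %
inside the target type's specific peaks, PP ~ Beta(2, 1), all
deterministic per seed).

Standard benchmark conditions: two cell types, `n = 10,000` fragments per
cell, `q = 0.3`, 500 cells per type (300 per type in the CI fixture to keep
the suite fast), against a 100,000-peak universe. The universe size is
chosen so that n/k matches the sparsity regime of real experiments
(~90 % zero entries here); a much smaller universe at the same n makes the
data unrealistically dense and the Z-score trivially accurate.
`evaluate_ranking` calls the top-P cells positive (P = the true positive
count) and reports accuracy, TPR and FPR at that cut, plus the
Mann–Whitney auROC with ties averaged.

What passing the synthetic benchmark shows: propagation recovers
trait-relevant cells that the sparse per-cell statistic misses, degrades
gracefully with noise, is calibrated under a degree-matched null, and is
insensitive to k and the seed cap. What it does not show: behavior under
batch effects, doublets, fragment-level artifacts, unbalanced or more
numerous cell types beyond those simulated, or real fine-mapping PP
distributions — the simulator models none of these, and real bulk
profiles differ from log-normal fabrications. The
`scripts/external_benchmark.py` path exists to rerun the same benchmark on
real sorted bulk data and real fine-mapped variants.

## Parameter defaults

| parameter | default | meaning |
| --- | --- | --- |
| `lsi.d` | 30 | retained LSI components |
| `lsi.tf_mode` | frequency | per-cell term-frequency normalization |
| `graph.k` | 30 | nearest neighbors per cell |
| `seeds.alpha` | 0.05 | upper-tail p cutoff for initial seeds |
| `seeds.cap_fraction` | 0.05 | maximum seed fraction |
| `scorer.n_background` | 50 | background iterations for the deviation Z |
| `propagation.gamma` | 0.05 | restart probability |
| `propagation.tol` | 1e-5 | convergence threshold (L1) |
| `propagation.max_iter` | 1000 | iteration guard |
| `trs.ceiling_quantile` | 0.99 | NP clipping quantile |
| `trs.top_fraction` | 0.01 | cells averaged into the TRS scale factor |
| `perm.B` | 1000 | permutations |
| `perm.alpha` | 0.05 | enrichment call cutoff |
| `sim.n` | 10000 | fragments per simulated cell |
| `sim.q` | 0.3 | simulation noise level |

## Numerical and degenerate-input choices

- Variant filtering is strictly greater-than (PP = 0.001 is dropped).
- A cell with zero open peaks is a fatal error at TF-IDF (divide-by-zero in
  the term frequency); the offending barcodes are listed.
- kNN distance ties break toward the lower cell index; seed-cap and top-Z
  ties likewise. All stochastic steps take explicit seeds.
- An all-constant NP vector yields an all-zero TRS with a warning.
- Exact score ties in the permutation test are counted by the ≤ indicator;
  note that on perfectly symmetric graphs the iterative solver realizes
  such ties only to within its convergence tolerance (~1e-6), so
  symmetric-graph p-values should be interpreted through the exact solver.
- `empirical p` can never be 0; the floor 1/(B+1) is attained exactly when
  the real score beats all permutations.

## Known limitations

- The built-in Z-scorer is not a drop-in numerical replica of any external
  deviation scorer; use the external-Z import for parity-critical work.
- Brute-force kNN is O(N²) in memory-bounded chunks; beyond a few hundred
  thousand cells an approximate backend would be needed (any plug-in must
  match the exact search at ≥ 99 % recall to preserve graph semantics).
- The permutation test is per-cell and uncorrected by design.
- Weighted (distance- or Jaccard-weighted) adjacency, alternative diffusion
  kernels, multi-trait joint propagation, fragment-file ingestion and peak
  calling are out of scope.
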