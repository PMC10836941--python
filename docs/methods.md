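# Methods

## The per-cell correlation strength index

For a gene–peak pair (x, y) over n cells with a row-stochastic cell–cell
weight matrix W, the index assigned to cell i is

L⁽ⁱ⁾ = n (x̃ᵢ − x̄)(ỹᵢ − ȳ) / ( √Σ(xᵢ − x̄)² √Σ(yᵢ − ȳ)² ),

with x̃ = W x the spatial lag. This is a local bivariate spatial-association
statistic of the Lee's-L family, transplanted from geography to the cell
neighborhood graph: it asks whether, in the neighborhood of cell i,
expression and accessibility deviate from their population means in the
same direction. The vectorized form over p pairs is
L = (W Z_Y) ∘ (W Z_X) with Z the column-z-scored feature matrices.

**z-scoring uses population variance (ddof 0).** The per-cell formula and
the vectorized Hadamard form are algebraically identical only when the
z-scores use the population denominator and W is row-stochastic: then
(W Z_x)ᵢ = (x̃ᵢ − x̄)/σ_x with σ_x = √(Σ(x − x̄)²/n), and the product of the
two lagged z-scores reproduces the n·(...)/(√·√·) expression exactly. The
oracle-equivalence test asserts this identity to 1e-10 and would fail under
sample (ddof 1) scaling.

Consequences worth knowing:

- With W = I the global index (column mean of L) equals Pearson's r with
  population scaling, exactly.
- |L⁽ⁱ⁾| is not bounded by 1; skewed features can push individual cells
  outside [−1, 1]. Only finiteness is guaranteed; plots clip colors to
  (−1, 1) by default because that is the interpretable scale.
- The index can be positive in cells where both features are *low* — it
  measures co-deviation from the mean, not activity.

## Weight matrix

W is built from a nonnegative connectivity matrix (typically WNN
connectivities; any nonnegative kernel is accepted) by setting the diagonal
to `self_weight` (default 1.0) and row-standardizing. `self_weight` is
exposed because connectivity scales differ between graph implementations;
with very large self weight the index degenerates toward plain Pearson
behavior. Cells with no neighbors become pure self-rows e_i, so their lag
is their own value and their contribution reduces to the Pearson term —
the graceful degenerate case.

## Dropout handling

Technical zeros become spurious *negative* z-scores after centering, which
biases the cross product. Two mitigations are provided: per-group feature
sparsity as a QC metric for excluding heavily zero-inflated features, and
an optional rule (`zero_dropouts`) that sets L[i, j] to 0 whenever the raw
(pre-transformation) gene or peak value of cell i is zero for that pair.
The stored per-pair global index is always the pre-zeroing column mean, so
zeroing changes the per-cell picture without silently redefining the
global statistic.

## Numerical choices

- Pairs whose gene or peak has zero variance are dropped with a warning
  rather than emitting NaN columns; an all-degenerate pair list is an
  error.
- Computation is chunked over pairs (default `chunk_size` 1000, a
  memory/throughput tradeoff). Dense chunks are materialized in Fortran
  order so per-column reductions have a layout-independent summation
  order; this makes L bitwise-identical across chunk sizes, which the test
  suite asserts for chunk sizes {1, 7, 1000}.
- Genomic intervals are 0-based half-open internally; GFF3/GTF input
  (1-based closed) is converted on read, BED is taken as-is. Peak ids are
  parsed from both the `chr1:100-200` and `chr1-100-200` dialects.

## Gene–peak pairing

A pair (gene, peak) is formed when the peak interval intersects the gene
body extended by `window_bp` on both sides (default 100 kb, a common
cis-regulatory window; it is a visible parameter, not a claim about
biology). Distances are measured from gene-body boundaries; strand is used
only to label peaks upstream/downstream of the gene. TF pairing intersects
peaks with binding-site intervals from a BED6 file whose name column must
resolve against the gene ids; unmatched names are logged and skipped, as
are genes absent from the annotation — real annotations are never
complete.

## Motif conversion

JASPAR PFMs are converted to Homer-style motif files with
p = (count + pseudocount)/(total + 4·pseudocount) per column (defaults:
pseudocount 0.5, threshold fraction 0.8). The detection threshold is the
stated fraction of the maximum attainable log-odds score against a uniform
background, Σ_pos log₂(max_p/0.25). The log base is a parameter
(`log_base`, default 2); Homer's own convention is the natural log, so set
`log_base=math.e` when the file is destined for Homer itself.

## Marker detection

Markers are detected on the columns of L: for each group, a two-sided
Wilcoxon rank-sum test of the group's cells against the rest (or against a
named second group), Benjamini–Hochberg correction across pairs within
each group's family, and a flag when q < α **and** |ΔL| ≥ `min_delta`
(defaults 0.05 and 0.1). A rank test was chosen because per-cell L values
are heavy-tailed; Student's t is available as an option.

A caveat the effect-size gate exists for: L values of neighboring cells
share lag terms and are therefore positively autocorrelated, so the rank
test's independence assumption is violated and raw p-values are
anticonservative (pseudo-replication). Under a fully null simulation the
fraction of pairs with q < 0.05 is far above 0.05, yet the fraction
passing the full marker rule is ~0 because null ΔL values are an order of
magnitude below `min_delta`. Interpret q-values jointly with ΔL, never
alone.

## Trajectory dynamics

Cells whose group label lies on the user-given path and whose pseudotime
is present are split into `n_bins` ordered bins (default 50), by equal
cell count (default; immune to empty bins) or equal pseudotime width
(errors on an empty bin, suggesting the alternative). Each pair's curve is
the exact per-bin mean of L; per-bin cell-type occupancy accompanies it.
Variability is the across-bin standard deviation of the binned curve;
"dynamic" pairs are those above mean + k·sd of all variabilities
(default k = 1) or the top-k. Both the statistic and the threshold are
deliberately simple and logged with the output. Gaussian smoothing
(bandwidth 1 bin) is applied to curves for display only, never before
variability scoring.

## SOM temporal modules

Dynamic curves are z-normalized per pair (flat curves excluded with a
warning) and clustered by a 1-D self-organizing map: `m_units` units
(default 3), Gaussian neighborhood with σ = m_units/2, learning rate 0.5,
both decaying linearly over 2000 single-sample update steps, codebook
initialized from data samples. The seed is mandatory — an unseeded SOM is
not reproducible, and identical seeds give identical assignments by
construction. Module ids are best-matching units; prototypes are the final
codebook curves on the normalized scale.

## The synthetic generator

The generator produces the study conditions under which the stack is
validated; it emulates the *statistical* structure the index assumes, not
chromatin biophysics:

- a 1-D latent trajectory t ~ U(0, 1) with cell groups occupying
  contiguous pseudotime segments (proportions configurable);
- a symmetrized Gaussian-kernel k-NN graph (default k = 15) built from the
  latent coordinates, so neighborhood quality is controlled (a
  `realistic_graph` mode rebuilds it from a PCA of the simulated data for
  integration testing);
- per designed pair, a shared latent factor modeling switch-like
  regulatory-program activity: iid noise diffused two steps over the graph
  and thresholded to ±1. The bimodal factor is deliberate — a smooth
  Gaussian factor would enter L as a χ²₁-distributed squared term and
  dominate binned-curve noise, whereas program-like on/off activity gives
  curves that track the designed coupling ρ(t, group) cleanly;
- gene/peak latents x = √|ρ| c + √(1−|ρ|) ε with c, ε, ε′ orthonormalized
  over cells, so constant designed couplings are *exact* on the latent
  scale (the ±0.05 recovery tolerance then absorbs only the declared
  distortions below);
- softplus transformation to a nonnegative expression-like scale, optional
  measurement noise (`noise_sd`, default 0.2), and Bernoulli zero-inflation
  per modality (`dropout_rate`, default 0.2, a moderate rate appropriate
  for features that passed sparsity QC).

What the generator does **not** emulate: count noise and library-size
variation, doublets, batch effects, peak co-accessibility structure,
trans-regulation, or graphs corrupted by modality-specific noise. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under its own assumptions, not performance on real tissue.

Scenario presets fix the conditions used throughout the tests: `null`
(1000 uncoupled pairs), `cluster_marker` (ρ = 0.8 in one group of 300
among 1200 cells plus 20 decoys), `ramp` (ρ(t) = 0.8t, 10 of 100 pairs),
`rise_fall` (ρ(t) = 0.8 sin πt), `repressive` (ρ = −0.6), `mixed_modules`
(30 rising + 30 rise-fall + 30 falling pairs) and `consistency` (500
constant couplings spanning ±0.9). Trajectory presets use 5000 cells so
that 50 equal-count bins average ~100 cells each — enough to resolve
monotone trends against neighborhood-scale noise; marker and null presets
use 1200 cells, and the consistency preset 2000.

## Design decisions that were genuinely open

- **One-vs-rest** marker families (with pairwise comparison available via
  `find_markers`); BH within each group's family.
- **Gene-body-anchored** windows rather than TSS-anchored; the distance
  definition is simple and symmetric, and a TSS mode would only relabel
  distances, not membership, for typical window sizes.
- Variability = across-bin SD of binned means. Fancier statistics
  (spline fits, autocorrelation) were rejected to keep the selection rule
  transparent and affine-equivariant.
- The HDF5 read path accepts only the X/obs/var/obsp(uns) slots of the
  common multimodal container dialect; everything else is ignored rather
  than modeled.

## Known limitations

- q-values from marker tests are anticonservative under spatial
  autocorrelation (see above); no spatial permutation null is implemented.
- The index has no per-cell significance measure; it is a descriptive
  decomposition of a global association.
- `pair_by_window` is O(genes × peaks-per-chromosome); fine for desk-scale
  and single-genome annotations, not optimized for millions of features.
- The SOM is 1-D by design (temporal orderings of modules); no 2-D grids.
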