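# Methods

This note documents the statistical procedure implemented by `clumpnet`,
the choices made where the design was genuinely open, and what the bundled
synthetic experiments do and do not demonstrate.

## Smoothing

For each cell, the k nearest cells in the supplied 2-D embedding
(Euclidean distance, self included, distance ties broken by cell index)
are averaged per gene and the decimal part truncated, so the smoothed
matrix is again a valid integer count matrix. Self-inclusion makes k = 1
the identity. Smoothing operates on raw counts — truncation to integers
only makes sense there — and k sets the effective resolution of the whole
analysis: populations of fewer than ~k cells are averaged away.

Smoothing deliberately re-uses each cell's neighborhood for every gene, so
it preserves gene–gene correlations while shrinking per-gene noise by
roughly 1/k. A consequence worth knowing: smoothed rows are not
independent observations. On data where the embedding carries no signal,
smoothing inflates the apparent evidence for chance correlations (see
*Null calibration* below).

## Resampled network inference

Each of M resamples draws N cells uniformly **without replacement**
(N defaults to 40 % of cells, capped at 20 000; bootstrap-with-replacement
is available behind a flag). Within a resample:

* **Variable genes (vst).** Per-gene mean and variance of raw counts; a
  tricube-weighted local quadratic (loess, span 0.3) of log₁₀ variance on
  log₁₀ mean over genes with positive variance; counts standardized by the
  trend-predicted standard deviation and clipped at √n; genes ranked by
  the variance of the standardized values. The loess is implemented
  in-package (vectorized batched weighted least squares); with fewer than
  five points it degrades to a local line so it never interpolates.
* **TF restriction.** The ranked list is intersected with the user's
  transcription-factor catalog; specimens with < 3 variable TFs are
  skipped (with a warning, reducing the effective M).
* **ARACNe.** Expression is discretized per gene into B equal-width bins
  (default B = ⌊√N⌋), mutual information is estimated for all pairs with
  the Miller–Madow bias-corrected plug-in estimator
  (Ĥ = Ĥ_plugin + (m−1)/(2n), m = occupied bins; MI in nats), negative
  estimates are clipped to zero, and the data processing inequality
  removes any edge that is strictly the weakest in some triangle
  (tolerance `dpi_eps`, default 0). A numba kernel computes the MI matrix;
  a pure-numpy path with identical output is used when numba is absent.

## Significance by gene-name shuffling

The null asks: how often would this gene (edge) appear if gene names
carried no information? Shuffling names K times in each of M̂ resamples
yields M̂·K shuffled specimens. Because variable-gene *selection* is
name-blind, the variance ranking is computed once per resample and shared
across its K shuffles — shuffle-then-select and select-then-relabel are
the same distribution.

* **Node rate.** Analytic: λ_node = n_hvg / n_genes.
* **Edge rate.** A specific TF pair essentially never recurs among a
  feasible number of shuffled specimens, so per-pair rates are degenerate;
  shuffling makes pairs exchangeable, and the implementation pools all
  edge occurrences into one rate λ_edge = (edges observed) / (specimens ×
  C), with C = C(|TF universe ∩ genes|, 2) held fixed across specimens.
  Per-pair rates remain available (`run_null_ensemble(..., pooled=False)`)
  for fidelity experiments.

Appearance counts over the M real specimens are tested with the upper
Poisson tail P(X ≥ count), X ~ Poisson(λM), adjusted by the
Benjamini–Yekutieli step-up (valid under arbitrary dependence) with nodes
and edges as separate families sized by the full TF universe and all
candidate pairs. The consensus network keeps nodes with q below the
threshold (default 10⁻⁵) and edges whose own q and both endpoints pass;
edge weights are the mean MI over the specimens containing the edge.

### Null calibration and its limits

On a structureless dataset (independent NB genes) the consensus network
should be empty, and the bundled calibration experiment verifies that it
is. Two caveats discovered while designing that experiment are genuine
properties of resampling a single dataset, not implementation artifacts:

* Resamples are overlapping subsets of one realized dataset, so the genes
  with the highest *realized* variance recur across specimens far more
  often than the Poisson independence model expects. With N at half the
  cells this produces occasional "significant" nodes on pure noise; at
  N = one-third of the cells (the lower end of the recommended range,
  used by the calibration experiment) the effect disappears at these
  problem sizes.
* Smoothing over a signal-free embedding correlates rows and amplifies the
  same effect; the calibration experiment therefore runs on raw counts,
  isolating the significance layer itself.

Both effects shrink as the dataset grows relative to N and are dominated
by real signal in structured data, but users analyzing small datasets with
aggressive smoothing should expect the extreme tail of the null to be
anti-conservative.

## Control nodes

Domination is closed-neighborhood on the undirected consensus graph:
minimize Σx_v subject to x_v + Σ_{u∈N(v)} x_u ≥ 1, x binary, solved
exactly with HiGHS through `scipy.optimize.milp` (deterministic). Isolated
vertices force themselves into every solution. Alternative optima are
enumerated by adding a no-good cut per optimum and re-solving while the
objective stays optimal (default 15 solutions, matching common practice of
repeated solves); enumeration guarantees *distinct* optima and stops early
when all optima are exhausted, which makes the critical / intermittent
classification well defined rather than solver-dependent: critical = in
every enumerated optimum, intermittent = in at least one but not all.

## Clump clustering and automatic k

Clumps are Louvain communities (igraph multilevel, seeded RNG) of the
standard log-normalize → PCA → kNN graph of the *original* counts,
computed at the highest resolution of a grid whose smallest community
still has ≥ ⌈0.8 k⌉ cells. Clump profiles are mean log-normalized
expression of the control genes (critical ∪ intermittent for the
automatic workflow; one MDS for the manual workflow); profiles use the
original rather than the smoothed counts by default (configurable).
Zero-variance clump profiles have undefined Pearson distance; the pipeline
drops such clumps with a warning and leaves their cells unassigned.

Ward clustering uses d = 1 − Pearson between profiles with the modern
squared-distance Ward update (scipy); the classic unsquared recurrence is
available as `variant="classic"` for cross-checking.

**Multiscale bootstrap.** For scales r ∈ {0.5, …, 1.4}, B resamples of
⌈r·p⌉ feature columns (with replacement) are re-clustered; BP_r(node) is
the fraction of bootstrap trees containing the node's exact clump set. AU
values come from the weighted least-squares fit of
z_r = v·√r̃ + c/√r̃ with z_r = Φ⁻¹(1 − BP_r) and binomial weights, over the
non-degenerate scales only (0 < BP < 1); AU = 1 − Φ(v − c). Nodes with
fewer than three usable scales fall back to the clipped BP at the scale
nearest 1 (so a node present in every bootstrap tree gets
AU = 1 − 1/(2B), and single-scale runs degrade to plain BP, flagged). The
root is excluded: its BP is identically 1, so bootstrap support carries no
information about it, and treating it as confident would collapse every
confident partition to a single cluster.

Confident clusters are the outermost internal nodes with AU ≥ 1 − α
(default α = 0.05); uncovered clumps stay unassigned. The cluster number
is the smallest k whose tree cut maximizes the ARI (Hubert–Arabie,
implemented from the contingency table and cross-checked against
scikit-learn) against the confident partition, with unassigned clumps as
singletons. Cells inherit their clump's label.

**Known behavior of the AU/ARI automatic k.** The AU extrapolation is
anti-conservative for nodes whose BP is small but rises steeply across
scales, and any grouping that the realized data pins exactly (for
example, two of three equidistant blocks happening to lie closer together)
is a *bootstrap-stable* cluster and can legitimately reach high AU even
though it sits above the "true" partition. On very cleanly separated
data the confident partition can therefore be coarser (superclusters) or
occasionally finer (locked-in sub-splits) than the planted one. The
block-profile experiment sizes (40 clumps × 40 features) were chosen so
that feature resampling has genuine variability — with very few features
the between-block hierarchy locks in and the experiment degenerates.
Consequently the automatic k is right in ≈95 % of runs on block profiles,
not 100 %.

**Automatic vs manual workflows on the bundled fixture.** On the planted
3-type fixture the types are separable enough that a k = 3 cut is
identical whether profiles use the ~40 control nodes or a single ~25-gene
MDS — with a stable k the two workflows produce literally the same
partitions. The automated workflow's advantage over manual-k /
per-replicate-MDS clustering therefore cannot manifest at this scale; it
belongs to the fine-grained regime (dozens of clusters, subtle
distinctions) where manual choices are subjective and MDS gene variation
moves cluster boundaries. What the replicate experiments at this scale do
show is that the significance filter makes the network itself far more
reproducible: the fraction of edges shared by all 10 replicates is ~8×
higher with selection than without, and MDS gene content overlaps much
more (Jaccard 0.63 vs 0.44).

## Synthetic data generator

The generator emulates the statistical shape of droplet scRNA-seq data:

* counts are negative binomial (Gamma–Poisson, var = μ(1+αμ), α = 0.5);
* background genes have lognormal means (σ = 1.5) spanning the whole
  expression range, so the variable-gene trend has reference genes at
  every mean;
* each cell type activates its regulators (log-fold effect 2.0) whose
  latent activity also varies within type (SD 1.0); each target's log-mean
  follows its regulator's activity plus Gaussian noise (SD 0.8). The
  within-type activity variance and target noise are what make the
  regulator the *most* informative neighbor of its targets, so DPI pruning
  resolves each program into the planted regulator→target forest rather
  than an arbitrary spanning tree;
* the TF catalog is the planted genes plus decoy TFs (20 % of genes), so
  the TF-restriction step is exercised;
* the embedding is type blobs on a circle (separation 10, spread 1).

What it does **not** emulate: dropout beyond NB sampling, batch effects,
doublets, continuous differentiation trajectories, or library-size
variation between cell types. Passing the bundled experiments shows the
machinery is correct and well calibrated under the stated generative
model, not that the defaults are optimal for any particular real dataset.

Default fixture scale — 1500 cells × 1000 genes, 3 types, 15 regulators,
150 planted edges, pipeline at M = 20, M̂ = 100, K = 10, n_hvg = 200,
N = 600 — keeps a full pipeline run under a minute on one CPU while
preserving the selected-fraction (n_hvg/n_genes = 0.2) and N/cells ratios
of full-size analyses. Production defaults for real data remain
M = 100, M̂ = 1000, K = 100, n_hvg = 2000, q < 10⁻⁵.

## Numerical and reproducibility notes

* Random streams derive from one master seed with per-purpose,
  per-specimen substreams, so the M and M̂ loops are order-independent.
* All fixtures are integer-seeded `numpy.random.Generator` draws —
  bitwise reproducible across platforms.
* Distance ties in smoothing, rank ties in gene selection, and linkage
  ties all break deterministically (stable sorts, fixed orders).
* p-values are clamped to the open interval (0, 1]; BY q-values support
  implicit p = 1 family members so only observed hypotheses are stored.
* Equal-width discretization maps each gene's maximum to the top bin and
  constant genes to bin 0; B < 2 is rejected.
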