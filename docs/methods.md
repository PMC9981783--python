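# Methods

This note documents the models, parameter choices and numerical conventions
behind `atacfuse`, what the synthetic generator does and does not emulate,
and the design decisions taken where several constructions were defensible.

## Modality construction

**TF-IDF / LSI.** The peak matrix is normalized as
`log(1 + TF·IDF·10⁴)` with `TF(p,c) = x_pc / depth_c` and
`IDF(p) = n / n_cells_with_peak_p`, the common scATAC formulation; plain
`TF·IDF` is available via `log_scale=False`. Because TF divides by the cell
total, the transform is exactly invariant to uniform per-cell depth scaling.
Peaks observed in no cell are dropped (warning); an all-zero cell is an
error that names the offending barcode. The truncated SVD keeps
`n_components` scores `U·S`; by default the first component is computed and
discarded, since it is dominated by sequencing depth. Component signs are
fixed so that each loading's largest-magnitude entry is positive, making
output reproducible across SVD backends.

**LDA.** Collapsed Gibbs sampling over binarized accessibility, cells as
documents and accessible peaks as words (cisTopic-style binarization).
Defaults: `alpha = 50 / n_topics`, `beta = 0.1`, 500 sweeps. Collapsed Gibbs
was chosen over variational inference for implementation transparency and
exact seed determinism; the inner sweep is JIT-compiled (numba) and the
sampler's RNG is seeded once, so a fixed seed yields identical output. The
returned embedding is the smoothed per-cell topic distribution
`(n_dk + alpha)` normalized to rows summing to one. We use 500 sweeps as the
default and 150–200 sweeps in the bundled benchmark routines, where the
planted structure is strong and the chain plateaus within ~50 sweeps.

**Gene activity.** A peak is assigned to a gene when it overlaps ≥ 1 bp of
the union of the gene body and a strand-aware promoter: `[TSS−u, TSS)`
upstream of '+' genes and `[TES, TES+u)` of '−' genes, with `u = 2000 bp`
by default (a conventional promoter width; the assignment window is a
single interval because the promoter abuts the body). Peaks overlapping
several genes contribute their full count to each — activity is a sum of
reads, not a partition of them. Reduction: per-cell normalization to a 10⁴
scale, `log1p`, per-gene centering/unit-variance scaling, PCA.

**Motif deviations.** For motif *j* with member set M_j, the raw deviation
in cell *c* is `(Σ_{p∈M_j} x_pc − Σ_{p∈M_j} q_p d_c) / Σ_{p∈M_j} q_p d_c`,
where `q_p` is peak *p*'s fraction of all reads and `d_c` the cell depth.
Two exact identities follow and are tested: a motif containing all peaks has
deviation 0 in every cell, and a matrix with uniform `q_p` and equal depths
gives deviation 0 everywhere. z-scores compare the observed deviation
against `B = 50` background sets, each sampling one replacement peak per
member peak (with replacement) from the same stratum of a
10 × 10 (GC-fraction × mean-accessibility) quantile grid;
accessibility-only strata are used when GC content is unavailable. This
stratified resampling replaces chromVAR's Mahalanobis-distance sampling — a
deliberate simplification with the same matching intent. Cells with zero
background standard deviation get z = 0 (warning). Before PCA the z matrix
is standardized per motif by default (`rescale_motif=False` skips the second
standardization; both orders are defensible and the choice is exposed).

**Component count.** `select_n_components` implements the elbow heuristic:
the interior index maximizing the second difference of the normalized
variance-explained curve, clipped to [2, len−1]. Permutation-based PC
significance testing is intentionally not implemented.

## Integration

**CPCA.** Each block is column-centered and divided by its Frobenius norm
(total variance) so that no modality dominates by scale — this normalization
is how the unit-sum constraint on block weights is realized; `scale_blocks=False`
disables it. The joint scores are the top-d left singular vectors (times
singular values) of the concatenation, hence exactly a second-step PCA; the
test suite checks this equivalence against an independent dense SVD to
≤ 1e-8 in principal angle.

**MultiCCA.** Maximizes `Σ_{i<j} wᵢᵀXᵢᵀXⱼwⱼ` under `w_kᵀX_kᵀX_kw_k = 1`.
Gram matrices carry a ridge (default 1e-6) for invertibility. Each block
update `w_k ∝ (X_kᵀX_k)⁻¹ X_kᵀ Σ_{j≠k} X_j w_j` is the exact constrained
maximizer given the other blocks, so the objective ascends monotonically
(asserted in tests). Further components deflate each X_k by projecting out
its canonical variate. For K = 2 the first component reproduces the
closed-form generalized-eigenvalue CCA solution to 1e-6.

*Joint embedding from variates.* The canonical variates are unit-variance by
construction whether or not a modality actually participates in a shared
direction, so a plain K-way average halves the signal-to-noise of any
component carried by only a subset of modalities. The joint embedding
therefore weights each modality's variate by its mean correlation with the
other variates of that component (clipped at zero, normalized); when all
variates correlate equally this reduces to the plain average. This mattered
in practice: with signal split across modality subsets (the complementary
design below), plain averaging degraded integrated clustering while the
weighted average recovers all populations.

**WNN.** For each cell and modality k, the cell's profile is predicted as
the mean of its `k_nn = 20` neighbors found within modality k, and as the
mean of its neighbors found in each other modality. The modality weight is
the softmax across k of the affinity ratio
`exp((e_cross − e_within)/σ_k(i))`, with a cell-adaptive bandwidth σ_k(i)
(distance to the `bandwidth_k`-th within-modality neighbor, floored at
1e-12 for duplicate cells); rows sum to one by construction, and two
identical modalities receive weight 1/2 each. The combined similarity
`θ(i,j) = Σ_k weight(i,k)·exp(−d_k(i,j)/σ_k(i))` ∈ [0,1] is kept for each
cell's top `k_nn` candidates, symmetrized by maximum, and edges with
neighborhood Jaccard overlap below 1/15 are pruned. Neighbor ties are broken
by lower cell index throughout.

Every integration output is invariant to the order in which modalities are
listed (exactly for CPCA scores up to sign and for the WNN graph; to
convergence tolerance for MultiCCA), which the tests verify by permuting the
modality list.

## Clustering, tree, trajectories

Embedding-kind joints are converted to a k-nearest-neighbor graph
(Euclidean, k = 20) whose edges are scored by neighbor-set Jaccard overlap;
edges below 1/15 are pruned and the surviving edges are clustered
**unweighted** with Leiden (default; Louvain available) at the requested
resolution. The graded Jaccard values encode a locality gradient inside
compact clusters that modularity optimization splits into spurious
sub-communities — we verified this over-splitting on well-separated
Gaussian blobs for the weighted construction — so they serve as a pruning
statistic rather than as edge weights (`binary=False` restores weighted
edges). WNN graphs are clustered directly on their similarity weights.
Cluster ids are relabeled contiguously by decreasing size; fixed seeds give
identical partitions.

The cluster tree clusters at each resolution of a grid (default 0.2–1.6,
step 0.2) and connects clusters at adjacent resolutions with
`in_proportion = |parent ∩ child| / |child|`; unstable clusters show cells
switching branches, i.e. low in-proportions. Per-node stability is the mean
fraction of the node's cell pairs that remain co-clustered at the other
resolutions — a co-membership stand-in for consensus-based stability
indices.

Trajectories use a deliberately simplified construction: a minimum spanning
tree over cluster centroids rooted at a user-supplied start cluster (no
automatic root selection), root-to-leaf paths as lineages, and pseudotime as
the arc-length position of each cell's orthogonal projection onto its
lineage's piecewise-linear centroid path. This preserves lineage topology
and coarse ordering but is not a principal-curve method: pseudotime is
piecewise-linear, and cells in clusters shared by several lineages are
assigned to the first lineage containing their cluster.

## Metrics

ARI, AMI (arithmetic normalization, hypergeometric expected MI) and
homogeneity are delegated to scikit-learn; the test suite validates all
three against exhaustive pair-counting/entropy enumeration. cLISI calibrates
per-cell Gaussian kernels to a target perplexity (default 30) by binary
search over all other cells; at perplexity ≥ n−1 the uniform kernel is the
exact maximum-entropy solution and is used directly. Per-cell values lie in
[1, number of types]. FOSCTTNN uses denominator n−2 (cells other than self
and the RNA nearest neighbor); distance ties count as "not closer", and
RNA-side ties resolve to the lower cell index. Changing the denominator to
n−1 would rescale values by (n−2)/(n−1), negligible at realistic n.
Agreement uses one fixed k per run (grid 50/100/150/200 by default, values
≥ n dropped). Summaries report q1, median, GMD, mean, sd (ddof = 1) and q3;
GMD is the mean absolute difference over ordered pairs, computed by the
sorted-coefficient identity.

## Synthetic data

The generator emulates the *structure* of a multimodal scATAC experiment,
not its full biology. Peaks tile one synthetic chromosome in three zones:
peak-only territory (no gene or motif covers it), motif territory (tiled by
motifs), and gene territory (tiled by gene bodies + promoters, alternating
strands). Cell depths are negative binomial (mean 2000, dispersion 10,
floored at 50); given its depth each cell's counts are multinomial over
per-type peak propensities: gamma background weights with the type's
`signal_fold` multiplier on its marker block (5 % of peaks by default). A
shared per-cell latent factor (type centroid + within-type deviation) drives
both the RNA embedding (latent + Gaussian noise) and, through its
within-type component only, a mild modulation of the ATAC marker signal —
coupling the between-type part would leak extra, seed-dependent fold
differences into the counts. Column sums equal sampled depths exactly, and
all draws come from named seeded streams, so outputs are byte-identical for
a fixed seed.

**What it does not emulate:** fragment-level Tn5 chemistry, doublets, batch
effects, realistic peak-width/GC structure (GC is uniform on [0.3, 0.7],
present only so background matching is exercised), or biologically derived
motif-peak assignments. Passing tests therefore demonstrate correctness of
the computational pipeline under a controlled generative model, not
performance claims about any real tissue.

**Complementary-signal design.** The design used to demonstrate the value of
integration plants four types such that no single modality separates every
pair: the first pair carries strong markers (fold 6) confined to the
peak-only zone — invisible to gene and motif aggregation; the second pair
carries weak, diffuse markers (fold 1.5 over 250 peaks, half in motif and
half in gene territory) plus a strong *shared* peak-only block. The weak
fold is chosen from the detection-threshold asymmetry between feature
spaces: pooling counts into ~40 genes or ~20 motifs preserves the total
signal-to-noise of the pair difference while the spiked-covariance detection
floor scales roughly with √(p/n), so the same signal sits below the floor of
the 5000-dimensional peak views (LSI and LDA merge the pair) and above the
floor of the pooled views (gene activity and motif deviations separate it).
Under these conditions, each unimodal clustering merges one pair (median
ARI ≈ 0.4–0.71 against the four planted types) while CPCA, MultiCCA and WNN
all recover all four types (median ARI ≥ 0.95 over seeds). The benchmark
uses n = 400 cells, 15 LSI components, 10 LDA topics (150 sweeps) and 5 PCs
each for the gene and motif views — the elbow scale of those matrices.

## Numerical conventions and degenerate inputs

Genomic intervals are 0-based half-open everywhere internally; GTF input is
converted at parse time, BED passes through. MTX files are 1-based per the
MatrixMarket standard (handled by scipy). Peak identity is the
`chrom:start-end` string in internal coordinates. SVD component signs follow
the largest-|loading|-positive rule. Zero-variance features are dropped with
warnings; duplicate cells floor WNN bandwidths at 1e-12; `d` larger than the
concatenation rank is truncated with a warning; non-convergent MultiCCA
returns its best iterate with a warning. Embedding TSVs are written with
17 significant digits so write→read round-trips are exact to ≤ 1e-12.

## Problem sizes

The bundled tests and the acceptance script run on synthetic problems of
100–500 cells and 400–5000 peaks (the complementary-design benchmark uses
400 cells × 5000 peaks over 5–10 seeds). These sizes were chosen so the full
suite exercises every code path, including the Gibbs sampler and background
resampling, while remaining comfortable on a single CPU core; the
implementation itself is vectorized/sparse and handles tens of thousands of
cells.

## Known limitations

- No batch correction, fragment-file input, or bin-based (peak-free)
  matrices.
- The MultiCCA deflation removes each component from the block columns by
  variate projection; canonical loadings for later components are expressed
  in the deflated basis.
- The trajectory module requires an embedding-kind joint representation; for
  WNN graphs, a UMAP of the graph is used (and for the geometric metrics on
  WNN, likewise), which imports stochastic layout structure beyond the graph
  itself despite being seeded.
- cLISI computes full pairwise distances (O(n²) memory) — appropriate up to
  a few thousand cells.
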