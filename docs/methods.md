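# Methods

## Model

`stacn` treats a tissue slice as an attributed cell network: vertices
are measurement units (spots or cells), a spatial adjacency `A` encodes
physical proximity, and an attribute matrix holds preprocessed
expression. Domain identification rests on two assumptions:

1. **Self-representation.** Cells of one spatial domain lie near a
   common low-dimensional subspace of expression space, so each cell's
   profile is approximately a linear combination of its domain-mates:
   `D ≈ D W` with `W` low-rank and block-structured. The same holds for
   the columns of a (sufficiently structured) spatial similarity.
2. **Structured noise.** Technical corruption is concentrated in
   cells, not spread uniformly: a damaged spot is wrong across many
   genes at once. An ℓ2,1 penalty over the cell axis of the stacked
   per-view residuals models exactly this — whole columns of noise.

The two learned networks are stacked into a third-order tensor
`W = [W_e, W_s] ∈ R^{n×n×2}` whose tensor Schatten p-norm couples
them: the t-SVD transform slices are `W_e + W_s` and `W_e − W_s`, so
penalizing their joint spectrum rewards agreement between the views
(common structure concentrates in the sum slice) while still permitting
view-specific detail in the difference slice. Cell features are the
truncated left factors of these two transform slices, scaled by the
square root of their singular values and row-normalized. The square
root scaling is a choice, not a derivation — features taken from the
factors unscaled or linearly scaled are one config flag away
(`features_from_networks`), and the scaling choice is deliberately
flagged here because nothing in the model fixes it.

## Preprocessing

Order: gene filter → library-size normalization → log1p → HVG selection
→ neighbor-mean augmentation → PCA.

* Genes expressed in fewer than 10 cells are removed.
* Cells are scaled to the **median library size**, then log1p. The
  median target is one common convention; any fixed target only shifts
  the log values by a constant.
* HVG: dispersion (variance/mean of normalized values) z-scored within
  20 equal-width mean bins, top 3000 genes, ties broken by gene order.
  Zero-dispersion genes are never selected while variable genes remain.
* Augmentation concatenates `[√(1−m)·X, √m·N X]` with `N` the
  row-normalized spatial adjacency and `m = 0.2`: each cell's features
  gain a 20%-variance summary of its spatial neighborhood. This is the
  neighbor-mean term of neighborhood-augmentation schemes; directional
  (azimuthal) components are intentionally omitted — the mean term
  carries the domain-membership signal and keeps the step parameter-free.
* PCA to 30 components, exact SVD, component signs fixed by making each
  component's largest-magnitude loading positive (bitwise
  reproducibility).

Whether HVG selection should precede or follow augmentation is not
determined by the model; this order (select on pure expression, then
augment) avoids selecting genes for their neighborhood smoothness.

## Spatial graph

K nearest Euclidean neighbors with weight `1/r`, symmetrized by
elementwise maximum so every retained edge keeps its stated weight;
k defaults to 5 for spot arrays and 8 for imaging platforms. Exact
all-pairs distances up to 20 000 cells (stable argsort, ties by cell
index), KD-tree beyond. Coinciding coordinates among selected neighbors
are refused rather than silently given infinite weight.

## Solver

One auxiliary tensor `J ≈ [W_e, W_s]` splits the Schatten term from the
constraints. Per iteration:

1. `J ← prox_{Schatten p, 1/μ}(W + Λ/μ)` — slice-wise singular value
   shrinkage in the transform domain (soft thresholding at p = 1,
   generalized soft-thresholding with Newton refinement for p < 1).
   Symmetric slices go through `eigh` rather than a full SVD.
2. `W_v ← argmin ‖M_v − M_v W − E_v + Y_v/μ‖² + ‖W − J_v + Λ_v/μ‖²`,
   a ridge-regularized linear solve, then projection onto symmetric
   hollow matrices (average with transpose, zero diagonal).
3. `E ←` column-wise ℓ2,1 shrinkage of the stacked residuals with
   threshold λ/μ (a cell is flagged noisy jointly across views).
4. Projections `P_v`: orthogonal Procrustes against the residual
   target. A square orthogonal `P` only rotates the noise basis (the
   objective is invariant), so projections are updated only when
   `proj_rank` is strictly below the view's feature dimension; the
   default is full rank, i.e. fixed identity projections.
5. Dual ascent; `μ ← min(μ_max, ρ μ)`.

Schedule: `μ0 = 1e−3`, `ρ = 1.2`, `μ_max = 1e8`, `max_iter = 400`.
Convergence requires **both** relative constraint residuals and the
`W = J` splitting residual below `tol_primal = 1e−6`. The splitting
residual matters: declaring convergence on data feasibility alone stops
the solver while the low-rank term is still being negotiated, and the
returned `W` is then essentially the first ridge solve. The schedule is
deliberately gentle for the same reason — the useful structure of `W`
forms while λ/μ and 1/μ are of the same order as the data; growing μ
too fast freezes the iterates before that window.

**Scaling and λ.** Both views are normalized to unit mean column norm
inside the solver (`normalize_views`), which makes the λ trade-off
scale-invariant and the two views commensurate in the joint noise term.
In these units the per-cell noise threshold is directly interpretable:
λ around 0.3 (the default) lets the networks absorb structure shared
across cells while cell-specific residual drains into `E`; values
above ~0.5 make noise so expensive that the networks also fit it, and
values near zero make noise free, collapsing `W` to zero. λ is the one
knob worth touching on new data.

**Spatial view behavior.** A hollow KNN adjacency is close to full
rank, so only its smooth low-frequency part is self-representable; at
the default λ most of the spatial view legitimately drains into `E_s`
and the spatial context reaches the features mainly through the
neighborhood augmentation of the expression view. On denser or
longer-range spatial similarities `W_s` carries more weight.

## Affinity and clustering

The affinity learner solves a nonnegative elastic-net
self-representation on the row-normalized features: per-column ℓ1
threshold `α · (strongest gram entry of that cell)` with `α = 0.3`,
ridge weight 2.0, FISTA, zero diagonal. Nonnegativity keeps
anti-correlated cells (typically other domains) out of the graph; the
ridge spreads weight over groups of correlated neighbors instead of
electing single representatives, which is what a modularity-based
partitioner needs; the adaptive threshold gives weakly-correlated cells
the same neighbor budget as hub cells. The symmetrized matrix is pruned
to each cell's 30 strongest neighbors and re-symmetrized by maximum.

Leiden (RB-configuration modularity, fixed seed, 2 iterations) is run
over resolutions 0.10 … 2.50 in steps of 0.01; the smallest resolution
yielding exactly the requested number of domains wins, otherwise the
closest count with a warning.

The `concat` pipeline mode replaces the joint tensor decomposition with
independent per-view matrix decompositions (the feature-concatenation
ablation); the `raw` mode skips denoising entirely and decomposes the
rectified-cosine expression similarity and the spatial adjacency.

## Metrics

ARI (permutation-model), NMI (arithmetic-mean normalization),
silhouette and Davies-Bouldin (scikit-learn, Euclidean), separation
(mean pairwise distance of domain centroids) and compactness (mean
distance of cells to their own centroid). Moran's I uses the graph
weights as given (no row standardization by default; an option exists)
and reduces a multi-dimensional embedding to the mean of per-dimension
values.

## Synthetic data

`generate_slice` emulates what the method consumes: a regular grid of
spots, contiguous domains (bands, blocks, or Voronoi cells of random
centers), per-gene baseline log-rates `N(log 2, 0.3)`, a marker-gene
log-lift of 1.0 for each domain's 10 markers, per-entry log-normal
noise (σ = 0.3), Poisson counts, and 20% independent dropout — the
log-normal-Poisson cascade gives overdispersed counts, dropout gives
zero inflation. Defaults: 20×20 grid, 4 banded domains, 200 genes. The
generator deliberately does not model platform-specific artifacts:
spatially correlated noise, barcode swapping between neighboring spots,
segmentation errors, or gene-gene correlation beyond the domain
structure. Passing tests therefore demonstrate correct mechanics and
recovery under idealized SRT-like noise, not performance on any real
platform. A plain k-means-on-PCA baseline reaches ARI ≈ 0.6 on these
fixtures, so the pipeline's ≥ 0.9 recovery reflects the method rather
than trivially separable data.

`generate_subspace_data` plants unit-norm columns in independent random
low-dimensional subspaces — the regime where self-representation
provably yields block-diagonal weights — and is used to test the solver
core in isolation. Its second view is the gram matrix with diagonal
kept: a hollow gram is full-rank and not self-representable, whereas
the full gram has rank equal to the summed subspace dimensions.

## Problem sizes and numerics

Tests and the acceptance script run at n = 100–400 cells, 60–200
genes, 10 simulation seeds — sizes at which a full run takes seconds
to a few tens of seconds on one core while still exhibiting every
qualitative behavior of interest. The t-SVD and proximal operators are
exact to ~1e−10 or better; the scalar Schatten prox for p < 1 refines
the generalized-threshold solution to 1e−10 by Newton iteration;
FISTA stops at a relative iterate change of 1e−8. Degenerate inputs are
refused early with named errors (duplicate coordinates, all genes
filtered, constant values in Moran's I, single-cluster silhouette).

## Limitations

* The Schatten exponent defaults to p = 1; p < 1 is implemented
  (generalized soft thresholding) but the solver's behavior under a
  nonconvex spectral penalty is less predictable and not exercised by
  the default pipeline.
* λ, α and the augmentation mix are fixed global constants; no
  per-dataset calibration is attempted.
* Multi-slice input is handled by stacking over shared genes with a
  batch label — no spatial registration between slices.
* Dense n×n linear algebra bounds practical problem size to a few
  thousand cells per run on one core.
* The ADMM is an inexact augmented-Lagrangian scheme for a nonconvex
  constrained problem: it converges to feasibility and (empirically) to
  useful stationary points, but no global-optimality claim is made, and
  the endpoint depends on the penalty schedule.
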