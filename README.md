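# stacn

Joint graph denoising and spatial-domain identification for spatially
resolved transcriptomics (SRT).

SRT platforms (10x Visium, Stereo-seq, imaging-based assays) measure
gene expression while preserving each spot's or cell's position in the
tissue, but the extra spatial workflow injects substantial technical
noise — dropout, swapped barcodes, damaged spots. Most analysis stacks
denoise the data in one step and cluster it into spatial domains in
another; `stacn` does both jointly: the noise model is informed by the
structure the downstream clustering needs, and the clustering operates
on networks from which cell-wise noise has been removed.

## The model

A slice is turned into an attributed cell network `G = {V, A, X}`: a
spatial K-nearest-neighbor graph `A` with inverse-distance edge weights
(`a_ij = 1/r_ij`; k = 5 for spot arrays, 8 for imaging platforms) and a
preprocessed expression matrix `X` (library-size normalization, log1p,
highly-variable-gene selection, neighbor-mean augmentation, PCA).

Two clean cell networks — expression `W_e` and spatial `W_s` — are
learned by self-representation with a shared low-rank constraint and a
structured noise term, solved by ADMM:

```
min  ‖[W_e, W_s]‖_Sp  +  λ ‖[E_e; E_s]‖_{2,1}
s.t. P_e D = P_e D W_e + E_e ,  W_e = W_eᵀ ,  P_e P_eᵀ = I
     P_s A = P_s A W_s + E_s ,  W_s = W_sᵀ ,  P_s P_sᵀ = I
```

Here `D` is the feature × cell expression matrix, `P_v` are
row-orthonormal projections, `‖·‖_Sp` is the tensor Schatten p-norm of
the 3-way network tensor `[W_e, W_s]` (p = 1 gives the tensor nuclear
norm, computed slice-wise in the DFT transform domain), and the ℓ2,1
norm on the stacked noise flags whole cells as noisy jointly across
views. Compatible cell features are the scaled left factors of the
tensor singular value decomposition of `[W_e, W_s]`; a sparse
nonnegative self-representation affinity graph is learned from them and
partitioned with Leiden under a resolution grid search
(0.10 … 2.50, step 0.01) targeting the requested number of domains.

## Worked example

```python
from stacn import SyntheticSpec, generate_slice, run_pipeline
from stacn.metrics import ari, nmi, morans_i

slice_ = generate_slice(SyntheticSpec(seed=1))   # 400 spots, 4 banded domains
result = run_pipeline(slice_, k_target=4, seed=1)

print(ari(slice_.labels, result.assignment.labels))
```

Running `python examples/01_simulate_and_cluster.py` prints:

```
slice: 400 spots x 200 genes, 4 planted domains
found 4 domains at Leiden resolution 0.18
ARI vs planted labels: 0.987
NMI vs planted labels: 0.980
Moran's I of the learned features over the spatial graph: 0.176
```

ARI/NMI near 1 mean the planted domains are recovered almost exactly;
the positive Moran's I confirms the learned features vary smoothly
across the tissue. The other scripts in `examples/` demonstrate the
subspace-recovery property of the network noise model and the on-disk
formats / command-line workflow.

## Command line

```bash
stacn simulate --grid 20x20 --domains 4 --seed 1 --out-dir fixture/
stacn run --counts fixture/matrix.mtx --coords fixture/coords.csv \
          --truth-labels fixture/labels.csv --k-domains 4 --out-dir out/
stacn evaluate --labels out/labels.csv --truth fixture/labels.csv
```

`run` accepts MatrixMarket triplets, dense delimited tables and the 10x
`tissue_positions` dialect, and writes domain labels, cell features,
the affinity graph, an optional denoised expression matrix and a
metrics report. Exit codes: 0 success, 2 usage, 3 data error, 4 numeric
failure.

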