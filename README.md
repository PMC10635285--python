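# topopca

Topological PCA for single-cell expression data: robust sparse principal
component analysis regularized by **persistent graph Laplacians**, with the
standard preprocessing, clustering/classification evaluation protocols, and
hyper-parameter search schemes, plus a synthetic-data generator so the whole
pipeline runs without any downloads.

## The problem

scRNA-seq matrices are extremely sparse (dropout), very high-dimensional
(tens of thousands of genes), and heterogeneous across cell types. Plain PCA
is the workhorse reduction before k-means clustering or kNN classification,
but it ignores the nonlinear geometry of the cell manifold, its dense
loadings are hard to interpret, and its squared loss is fragile to outlier
cells. Graph-Laplacian-regularized PCA injects geometry, but only at a single
neighborhood scale.

## The model

With ``X ∈ ℝ^{M×N}`` (genes × cells), loadings ``U ∈ ℝ^{M×m}`` and an
orthonormal embedding ``Q ∈ ℝ^{N×m}`` (``QᵀQ = I_m``), the full objective is

```
min_{U,Q}  ‖X − UQᵀ‖_{2,1}  +  β‖Q‖_{2,1}  +  γ·Tr(Qᵀ (PL) Q)
```

* the **L2,1 reconstruction loss** sums per-cell residual norms, so a few
  aberrant cells cannot dominate the fit (replace by ``‖·‖²_F`` for the
  classical loss);
* ``β‖Q‖_{2,1}`` drives rows of the embedding toward zero (sparsity);
* ``PL = Σ_t ζ_t L^t`` is the **accumulated persistent Laplacian**: a
  filtration builds a nested sequence of graphs over the cells, each step
  contributes its 0-order graph Laplacian ``L^t``, and non-negative weights
  ``ζ_t`` consolidate all scales into one regularizer. Two filtrations are
  provided — a distance-threshold sweep over Gaussian-kernel kNN edge weights,
  and a scale-free sweep of the neighbor count k = 1…p itself (the
  kNN-induced variant, which needs no kernel bandwidth and shrinks the ζ
  search space from ``(p+1)^p`` to ``2^p`` candidates).

Setting terms to zero recovers the whole family: PCA, sparse PCA (sPCA),
graph-Laplacian sparse PCA (gLSPCA), its robust variant (RgLSPCA), and the
two topological variants (tPCA, kNN-tPCA). One IRLS majorize–minimize solver
with a Stiefel-manifold quadratic subproblem handles all six; the objective
trace is monotonically non-increasing.

## Worked example

```
$ topopca simulate --n-classes 3 --cells-per-class 50 --n-genes 500 \
    --separation 5 --dropout 0.4 --seed 0 --out-dir demo/data
wrote 500x150 counts to demo/data

$ topopca cluster-eval --matrix demo/data/counts.mtx --labels demo/data/labels.csv \
    --method knn-tpca --p 8 --n-runs 10 --out-dir demo/eval
knn-tpca: mean ARI 1.0000, mean NMI 1.0000

$ topopca fit --matrix demo/data/counts.mtx --method knn-tpca --m 3 --p 8 \
    --out-dir demo/fit
fit knn-tpca: 68 iterations, objective 2919.67, converged=True
```

The first command generates a 500-gene × 150-cell count matrix with three
cell classes, strong class structure (log-mean separation 5 within-cluster
standard deviations) and 40 % dropout. `cluster-eval` preprocesses it (log1p,
low-variance gene removal, z-scoring), reduces to 3 dimensions with
kNN-induced topological PCA (8 filtration steps, universal weights
ζ_t = 1/t), then runs k-means 10 times; mean adjusted Rand index and
normalized mutual information of 1.0 mean the three classes are recovered
perfectly in every run. `fit` exposes the embedding itself
(`embedding.csv`, `model.npz`); the objective value is the final robust
reconstruction + regularization cost, and the monotone trace is stored in the
archive.

The same functionality is available as a library:

```python
from topopca import (SyntheticSpec, simulate_counts, preprocess, zscore,
                     ModelConfig, cluster_eval)

xm = zscore(preprocess(simulate_counts(SyntheticSpec(seed=0))))
report = cluster_eval(xm, ModelConfig.from_method("knn-tpca", m=3, p=8),
                      n_runs=10, seed=1)
print(report.mean_ari)   # 1.0
```

Other subcommands: `classify-eval` (kNN classification over a grid of
subspace dimensions, macro precision/recall/F1), `grid-search` (the ζ/γ
search schemes), `rs-scores` (residue–similarity export), `laplacian`
(filtration export as Matrix Market), `preprocess`.

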