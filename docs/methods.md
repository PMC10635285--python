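# Methods

## Data model and preprocessing

The package works on a dense genes-by-cells matrix ``X ∈ ℝ^{M×N}`` with
optional per-cell class labels. Raw counts go through a fixed chain:
(1) natural ``log1p``; (2) entries below a floor (default ``1e-6``) set to 0;
(3) the lowest-variance fraction of genes dropped (default 20 %, count
``floor(frac·M)``, variance ties resolved toward keeping the smaller row
index); (4) cells whose class has fewer than 15 members removed (skipped with
a warning for unlabeled data). The floor is applied *after* the log
transform, following the stated order of the protocol the chain reproduces.
z-scoring is a separate step: per-gene demean and division by the
*population* (ddof = 0) standard deviation — the convention is immaterial to
the methods, and fixing it makes tests exact; zero-variance genes are left at
0 and flagged rather than dividing by zero. Model fitting assumes its input
is already z-scored and never re-centers.

## Graphs and filtrations

The cell graph is a union-symmetrized kNN graph (edge when either endpoint
is among the other's k nearest; default k = 15) with Gaussian edge weights
``W_ij = exp(−‖x_i−x_j‖²/η)``. The bandwidth η defaults to the mean squared
distance to the k-th nearest neighbor ("auto"), which keeps typical weights
well inside (0, 1); any positive constant can be supplied instead. Neighbor
ties at equal distance are broken toward the smaller point index, so graph
construction is fully deterministic.

Two filtrations produce the nested Laplacian sequence ``L^1 … L^p``:

* **Distance mode** (default p = 7): over the supported (W > 0) off-diagonal
  Laplacian entries ``l_ij = −W_ij``, compute ``l_min``, ``l_max``,
  ``d = l_max − l_min``; step t keeps edge (i,j) iff
  ``l_ij ≤ (t/p)·d + l_min``. Strong (close) edges enter first, edge sets are
  nested increasing, and step p contains the full supported edge set — the
  Vietoris–Rips-style behavior the construction is meant to mimic. A variant
  with the opposite orientation (edges *removed* below the threshold, giving
  a shrinking sequence) is available as
  ``inverted=True`` for comparison; the package default is the
  VR-consistent orientation. Thresholding is restricted to kNN-supported
  entries; ``l_min/l_max`` likewise range over supported edges only. When all
  weights are equal (d = 0) every step is the full supported graph, which is
  valid and tested.
* **kNN mode** (default p = 8): step k is simply the unweighted Laplacian of
  the union-symmetrized k-NN graph, k = 1…p. The printed directional rule
  (j ∈ N_k(i)) is symmetrized by union so every ``L^k`` is symmetric PSD.
  No bandwidth or threshold is involved.

The accumulated regularizer is ``PL = Σ_t ζ_t L^t`` with ζ_t ≥ 0 (negative
weights rejected; an all-zero ζ warns and returns the zero matrix). The
universal default is ζ_t = 1/t. ``betti0`` counts kernel eigenvalues below
``1e-8 · max(1, λ_max)`` — a relative tolerance that separates graph-Laplacian
spectral gaps at double precision for N up to ~10⁴ — and equals the
connected-component count (verified against a union-find oracle).

## Solver

No closed form exists for the L2,1 objective, so the solver is a
majorize–minimize scheme:

* Both L2,1 terms are majorized by weighted quadratics (IRLS): a residual
  column norm ‖e_j‖ is bounded by ``‖e_j‖²·d_j + 1/(4 d_j)`` with
  ``d_j = 1/(2·max(‖e_j‖₀, ε))``, ε = 1e-8. The same construction with row
  norms of Q gives the sparsity weights ``s_j``. For the Frobenius loss the
  residual weights are identity.
* **U-step** (closed form): ``U = X·D·Q·(QᵀDQ)⁻¹`` with ``D = diag(d)``.
  An alternative reading (``U = XQ`` each iteration) is available as
  ``simple_u_step=True``.
* **Q-step**: the reconstruction curvature ``q_jᵀUᵀUq_j`` is further
  majorized through ``λ_U = λ_max(UᵀU)`` with the standard touching
  correction at the current iterate, leaving a quadratic
  ``Tr(QᵀAQ) − 2Tr(QᵀB)`` with ``A = λ_U·D + β·S + γ·PL`` (diagonal plus the
  Laplacian) and ``B = D·(XᵀU + Q₀(λ_U·I − UᵀU))``. It is minimized on the
  Stiefel manifold by generalized power iteration: with
  ``α = λ_max(A)·(1+1e-6)``, iterate ``M = 2(αI−A)Q + 2B``, ``Q ← polar(M)``
  (SVD fallback if the polar factorization fails); each sweep is
  non-increasing.

Initialization is the top-m right singular subspace of X with a fixed sign
convention (largest-magnitude entry of each vector made positive), so fits
are deterministic with no random state. Outer iteration stops when the
relative objective change drops below ``tol`` (default 1e-6) or at
``max_iter`` (default 300). Monotone descent is provable on the ε-smoothed
surrogate; because the trace records the *unsmoothed* objective, a guard
terminates if it ever increases (only possible through the ε gap, at the
1e-12 level), so the recorded trace is always non-increasing. After
convergence Q is re-orthonormalized if its Gram drift exceeds 1e-8 (in
practice it stays at ~1e-15).

Default ``tol = 1e-6`` trades accuracy for speed; reproducing an
eigen-subspace to ~1e-6 principal angle (as the solver tests do) requires
tightening to ``tol ≈ 1e-12`` with a larger ``max_iter`` — both are ordinary
config fields.

Out-of-sample cells are projected by least squares in the learned basis,
``transform(U, X') = X'ᵀU(UᵀU)⁻¹``; for plain PCA this reproduces the
training embedding Q exactly.

## Evaluation protocols

* **Clustering**: reduce to m = number of classes, run scikit-learn k-means
  (k-means++ with ``n_init = 150`` restarts) ``n_runs = 30`` times with seeds
  ``seed + run``, report per-run and mean ARI/NMI. ARI uses the exact
  binomial-coefficient contingency form; NMI is MI normalized by the
  arithmetic mean of the two entropies (natural logs; conventions: both
  partitions trivial → 1, exactly one trivial → 0). Both are verified against
  independent brute-force oracles.
* **Classification**: per subspace dimension (default grid 100, 90, …, 10, 1,
  clipped to the data), fit on a stratified 60 % training split, project both
  splits with ``transform``, classify test cells by majority-vote kNN
  (default k = 5, ties to the nearest neighbor), score macro
  precision/recall/accuracy and macro-F1 = harmonic mean of the macro
  averages (deliberately not the mean of per-class F1s). The protocol is
  ``n_repeats × n_folds`` independent stratified splits (defaults 5 × 5) —
  the cross-validation design here is genuinely underdetermined by the usual
  description of "60/40 split with 5-fold CV", so both knobs are exposed.
  Classes smaller than ``n_folds`` are dropped with a warning.
* **Residue–similarity scores**: ``R_i`` is each cell's summed distance to
  all cells outside its class, normalized by the per-class maximum (global
  normalization behind a flag); ``S_i`` averages ``1 − d/d_max`` over the
  cell's own class, *including* the self term (matching the summation over
  the whole class; an ``include_self=False`` flag excludes it). Single-class
  input yields NaN residues with a warning; coincident data (d_max = 0)
  yields S = 1 by convention.

## Hyper-parameter search

For p filtration steps and a γ grid of size G, three exhaustive schemes:
*full* — every ζ_t ∈ {1, 1/2, …, 1/p, 0}, (p+1)^p·G combinations; *limited* —
m explicit triples of connectivity scales (default close/middle/long-range
blocks), the chosen three ζ's ranging over the p+1 candidates and all others
zero, m·(p+1)³·G; *knn* — every ζ_t ∈ {0, 1}, 2^p·G. At p = 8 the knn scheme
costs 2⁸/(3·9³) ≈ 0.117 of the limited scheme — less than a fifth. The γ
grid default spans 10⁻¹⁰…10¹⁰ log-uniformly, 5 points per pair of decades
(the spacing within those bounds is a package choice). Grid points are
scored by clustering agreement at a reduced 5 k-means runs; the winner is
re-scored at the full protocol; ties go to the earlier grid index.

## Synthetic data

The generator emulates exactly the data properties the models target —
cluster structure, dropout sparsity, magnitude-outlier cells — with a
log-normal count model chosen for analytic control of separation: informative
genes (default 10 %) receive class-specific log-means drawn from a Gaussian
with spread ``cluster_separation`` in units of the within-cluster log-sd
(fixed at 1); counts are ``round(exp(log-mean + noise))``; dropout zeroes
entries independently at the configured rate; outlier cells are scaled ×20.
It makes no attempt to match real library-size or gene-detection
distributions, batch effects, or negative-binomial overdispersion — passing
tests demonstrate correct mechanics and the claimed qualitative behaviors
(robustness of the L2,1 loss, value of multiscale regularization on
dropout-sparse data), not performance on any real dataset.

Deterministic toy fixtures back the worked examples: ``line4`` (1-D points
0, 1, 3, 7), ``two_blocks`` (K2 ⊕ K3 Laplacian, Betti-0 = 2),
``three_weights`` (3-node graph with weights 0.9/0.5/0.2, whose 3-step
distance filtration has edge counts 1, 2, 3).

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic matrices of up to
1000 genes × 300 cells — large enough to exercise every code path and the
statistical claims, small enough to run in seconds. Key tolerances: Laplacian
row sums |·| < 1e-10 and PSD within 1e-8 relative; embedding orthonormality
1e-8; objective monotonicity slack 1e-10 relative; IRLS ε = 1e-8. Degenerate
inputs handled explicitly: all-equal edge weights (full graph at every
filtration step), zero-variance genes (zeroed and flagged), all-zero ζ
(warning + zero matrix), rank-deficient loadings in ``transform``
(pseudo-inverse + warning), classes smaller than the fold count (dropped with
a warning).

## Known limitations

Only 0-order (graph) Laplacians are implemented — no higher-order simplicial
boundary operators, persistence pairs, or barcodes; Betti-0 per filtration
step is the only topological invariant exposed. The solver is a local
majorize–minimize scheme: it guarantees monotone descent, not a global
optimum of the nonconvex objective. Comparator reductions (UMAP, t-SNE, NMF)
are not reimplemented; external embeddings can be scored side-by-side by
exporting them to CSV and using the metrics module directly.
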