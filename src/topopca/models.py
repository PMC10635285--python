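"""Unified solver for the topological PCA family.

One objective covers six named methods.  With data ``X ∈ R^{M×N}`` (genes ×
cells), loadings ``U ∈ R^{M×m}`` and an orthonormal embedding ``Q ∈ R^{N×m}``
(``QᵀQ = I_m``), minimize

    loss(X − UQᵀ)  +  β‖Q‖_{2,1}  +  γ·Tr(Qᵀ · PL · Q)

where ``loss`` is either the squared Frobenius norm or the column-wise
L2,1 norm (sum of per-cell residual 2-norms — robust to outlier cells),
``‖Q‖_{2,1}`` is the sum of row 2-norms of Q (row-sparse embedding), and
``PL`` is a graph or accumulated persistent Laplacian over the cells.

Method presets (the identity table):

====================  ==========  ======  ======  ================
method                loss        β       γ       Laplacian
====================  ==========  ======  ======  ================
pca                   frobenius   0       0       none
spca                  frobenius   >0      0       none
glspca                frobenius   >0      >0      single graph L
rglspca               l21         >0      >0      single graph L
tpca                  l21         >0      >0      PL (distance filtration)
knn-tpca              l21         >0      >0      PL (kNN filtration)
====================  ==========  ======  ======  ================

No closed-form solution exists for the L2,1 terms; the solver is an
iteratively-reweighted least squares (IRLS) majorize–minimize scheme: both
L2,1 norms are majorized by weighted quadratics, the U-step is then closed
form, and the Q-step is an orthogonality-constrained quadratic solved by
generalized power iteration on the Stiefel manifold.  The objective trace is
non-increasing by construction (an explicit guard stops iteration on the rare
ε-smoothing violation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import polar

from .graph_filtration import (
    DEFAULT_K,
    DEFAULT_P_DISTANCE,
    DEFAULT_P_KNN,
    accumulate,
    distance_filtration,
    gaussian_adjacency,
    knn_filtration,
    reciprocal_zeta,
)

_METHOD_PRESETS = {
    "pca": dict(loss="frobenius", beta=0.0, gamma=0.0, laplacian_mode="none"),
    "spca": dict(loss="frobenius", beta=1.0, gamma=0.0, laplacian_mode="none"),
    "glspca": dict(loss="frobenius", beta=1.0, gamma=1.0, laplacian_mode="graph"),
    "rglspca": dict(loss="l21", beta=1.0, gamma=1.0, laplacian_mode="graph"),
    "tpca": dict(loss="l21", beta=1.0, gamma=1.0, laplacian_mode="pl_distance"),
    "knn-tpca": dict(loss="l21", beta=1.0, gamma=1.0, laplacian_mode="pl_knn"),
}


@dataclass
class ModelConfig:
    """Solver configuration.

    Parameters
    ----------
    m : target embedding dimension.
    beta : row-sparsity weight on ‖Q‖_{2,1} (β ≥ 0).
    gamma : Laplacian regularization weight (γ ≥ 0).
    loss : "frobenius" (squared) or "l21" (robust, per-cell).
    laplacian_mode : "none", "graph" (single Gaussian-kNN Laplacian),
        "pl_distance" or "pl_knn" (accumulated persistent Laplacian).
    p : number of filtration steps (persistent modes).
    zeta : length-p filtration weights; None → ζ_t = 1/t.
    k : neighbor count for the single-scale graph.
    eta : Gaussian kernel scale, or "auto".
    epsilon : IRLS safeguard for vanishing norms.
    max_iter, tol : outer-loop stopping (relative objective change).
    simple_u_step : if True, use U = XQ instead of the residual-weighted
        closed form (alternative reading of the unstated solver).
    seed : recorded for provenance; the fit itself is deterministic.
    """

    m: int = 2
    beta: float = 0.0
    gamma: float = 0.0
    loss: str = "frobenius"
    laplacian_mode: str = "none"
    p: int | None = None
    zeta: np.ndarray | None = None
    k: int = DEFAULT_K
    eta: float | str = "auto"
    epsilon: float = 1e-8
    max_iter: int = 300
    tol: float = 1e-6
    max_inner: int = 30
    simple_u_step: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.loss not in ("frobenius", "l21"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.laplacian_mode not in ("none", "graph", "pl_distance", "pl_knn"):
            raise ValueError(f"unknown laplacian_mode {self.laplacian_mode!r}")

    @classmethod
    def from_method(cls, method: str, m: int, **overrides) -> "ModelConfig":
        """Build a config from a named preset (see module docstring table)."""
        if method not in _METHOD_PRESETS:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(_METHOD_PRESETS)}"
            )
        kwargs = dict(_METHOD_PRESETS[method])
        kwargs.update(overrides)
        return cls(m=m, **kwargs)

    @property
    def method_name(self) -> str:
        for name, preset in _METHOD_PRESETS.items():
            if (
                preset["loss"] == self.loss
                and preset["laplacian_mode"] == self.laplacian_mode
                and (preset["beta"] > 0) == (self.beta > 0)
                and (preset["gamma"] > 0) == (self.gamma > 0)
            ):
                return name
        return "custom"


@dataclass
class EmbeddingResult:
    """Fitted loadings U (M×m), orthonormal embedding Q (N×m), and trace."""

    U: np.ndarray
    Q: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool
    config: ModelConfig | None = None
    PL: np.ndarray | None = None


def _row_norms(A: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(A * A, axis=1))


def objective(
    X: np.ndarray,
    U: np.ndarray,
    Q: np.ndarray,
    config: ModelConfig,
    PLmatrix: np.ndarray | None = None,
) -> float:
    """Evaluate the (unsmoothed) model objective at (U, Q)."""
    M, N = X.shape
    if U.shape[0] != M or Q.shape[0] != N or U.shape[1] != Q.shape[1]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, U {U.shape}, Q {Q.shape}"
        )
    E = X - U @ Q.T
    if config.loss == "frobenius":
        recon = float(np.sum(E * E))
    else:
        recon = float(np.sum(np.sqrt(np.sum(E * E, axis=0))))  # column 2-norms
    val = recon
    if config.beta > 0:
        val += config.beta * float(np.sum(_row_norms(Q)))
    if config.gamma > 0 and PLmatrix is not None:
        val += config.gamma * float(np.trace(Q.T @ PLmatrix @ Q))
    if not np.isfinite(val):
        raise FloatingPointError("objective is non-finite")
    return val


def irls_weights(residual_norms: np.ndarray, epsilon: float) -> np.ndarray:
    """IRLS majorization weights d_j = 1 / (2·max(‖e_j‖, ε))."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    norms = np.asarray(residual_norms, dtype=float)
    return 1.0 / (2.0 * np.maximum(norms, epsilon))


def stiefel_quadratic_minimize(
    A: np.ndarray,
    B: np.ndarray,
    Q0: np.ndarray,
    max_inner: int = 30,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize Tr(QᵀAQ) − 2·Tr(QᵀB) over orthonormal Q by generalized power
    iteration: with α ≥ λ_max(A), iterate M = 2(αI − A)Q + 2B, Q ← polar(M).

    Each sweep is non-increasing in the subproblem objective; iteration stops
    when the objective stalls.  Falls back to SVD orthonormalization when the
    polar intermediate is rank deficient.
    """
    A = np.asarray(A, dtype=float)
    Q = np.asarray(Q0, dtype=float)
    alpha = float(np.linalg.eigvalsh(A)[-1]) * (1 + 1e-6) + 1e-12
    shifted = alpha * np.eye(A.shape[0]) - A

    def sub_obj(Qc):
        return float(np.trace(Qc.T @ A @ Qc) - 2.0 * np.trace(Qc.T @ B))

    prev = sub_obj(Q)
    for _ in range(max_inner):
        Mmat = 2.0 * shifted @ Q + 2.0 * B
        try:
            Qn, _ = polar(Mmat)
        except np.linalg.LinAlgError:
            Qn = None
        if Qn is None or not np.all(np.isfinite(Qn)):
            u, _, vt = np.linalg.svd(Mmat, full_matrices=False)
            Qn = u @ vt
        cur = sub_obj(Qn)
        if cur > prev + 1e-12 * max(1.0, abs(prev)):
            break  # numerical stall; keep previous iterate
        Q = Qn
        if prev - cur <= tol * max(1.0, abs(prev)):
            prev = cur
            break
        prev = cur
    return Q


def build_laplacian_term(X: np.ndarray, config: ModelConfig) -> np.ndarray | None:
    """Construct the N×N Laplacian regularizer over cells per laplacian_mode.

    Cells are the columns of X; pairwise geometry is computed on the cell
    vectors (columns).
    """
    if config.laplacian_mode == "none" or config.gamma == 0:
        return None
    points = X.T  # cells as rows
    n = points.shape[0]
    k = min(config.k, n - 1)
    if config.laplacian_mode == "graph":
        return gaussian_adjacency(points, k=k, eta=config.eta).L
    if config.laplacian_mode == "pl_distance":
        p = config.p if config.p is not None else DEFAULT_P_DISTANCE
        graph = gaussian_adjacency(points, k=k, eta=config.eta)
        filt = distance_filtration(graph, p=p)
    else:  # pl_knn
        p = config.p if config.p is not None else DEFAULT_P_KNN
        p = min(p, n - 1)
        filt = knn_filtration(points, p=p)
    zeta = config.zeta if config.zeta is not None else reciprocal_zeta(filt.p)
    return accumulate(filt, np.asarray(zeta, dtype=float)).PL


def _svd_init(X: np.ndarray, m: int) -> np.ndarray:
    """Top-m right singular subspace with a deterministic sign convention."""
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    Q = vt[:m].T.copy()
    for c in range(Q.shape[1]):
        j = int(np.argmax(np.abs(Q[:, c])))
        if Q[j, c] < 0:
            Q[:, c] = -Q[:, c]
    return Q


def fit(X: np.ndarray, config: ModelConfig) -> EmbeddingResult:
    """Fit the configured model to X (genes × cells).

    X is assumed already preprocessed/z-scored; no centering is applied here.
    Deterministic: SVD initialization with a fixed sign convention, no random
    draws.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    M, N = X.shape
    if config.m > N:
        raise ValueError(f"m={config.m} exceeds the number of cells N={N}")
    PL = build_laplacian_term(X, config)

    Q = _svd_init(X, config.m)
    U = X @ Q  # QᵀQ = I
    eps = config.epsilon
    trace = [objective(X, U, Q, config, PL)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # (a) per-cell residual weights (identity for the Frobenius loss)
        E = X - U @ Q.T
        if config.loss == "l21":
            col_norms = np.sqrt(np.sum(E * E, axis=0))
            d = irls_weights(col_norms, eps)
        else:
            d = np.ones(N)

        # (c) weighted closed-form U-step
        if config.simple_u_step:
            U = X @ Q
        else:
            DQ = Q * d[:, None]
            G = Q.T @ DQ
            U = X @ DQ @ np.linalg.solve(G, np.eye(config.m))

        # (b) row-sparsity weights on Q
        if config.beta > 0:
            s = irls_weights(_row_norms(Q), eps)
        else:
            s = None

        # (d) Stiefel quadratic Q-step on the majorized surrogate:
        #   A = λ_U·D + β·S + γ·PL,  B = D·XᵀU + D·Q₀(λ_U·I − UᵀU)
        UtU = U.T @ U
        lam_u = float(np.linalg.eigvalsh(UtU)[-1])
        Adiag = lam_u * d
        if s is not None:
            Adiag = Adiag + config.beta * s
        A = np.diag(Adiag)
        if PL is not None:
            A = A + config.gamma * PL
        B = (X.T @ U + Q @ (lam_u * np.eye(config.m) - UtU)) * d[:, None]
        Q_new = stiefel_quadratic_minimize(A, B, Q, max_inner=config.max_inner)

        obj_new = objective(X, U, Q_new, config, PL)
        if obj_new > trace[-1] * (1 + 1e-12) + 1e-15:
            # ε-smoothing gap produced a (tiny) true-objective increase: stop
            converged = True
            break
        Q = Q_new
        trace.append(obj_new)
        rel = abs(trace[-2] - trace[-1]) / max(1.0, abs(trace[-2]))
        if rel < config.tol:
            converged = True
            break
    ortho_err = np.linalg.norm(Q.T @ Q - np.eye(config.m))
    if ortho_err > 1e-8:
        u, _, vt = np.linalg.svd(Q, full_matrices=False)
        Q = u @ vt
    return EmbeddingResult(
        U=U, Q=Q, objective_trace=trace, n_iter=it, converged=converged,
        config=config, PL=PL,
    )


def transform(U: np.ndarray, X_new: np.ndarray) -> np.ndarray:
    """Least-squares coordinates of new cells in the learned basis:
    ``X_newᵀ · U · (UᵀU)⁻¹`` (pseudo-inverse with a warning when U is
    rank deficient)."""
    U = np.asarray(U, dtype=float)
    G = U.T @ U
    if np.linalg.matrix_rank(G) < G.shape[0]:
        warnings.warn("rank-deficient loadings; using pseudo-inverse", stacklevel=2)
        return X_new.T @ U @ np.linalg.pinv(G)
    return X_new.T @ np.linalg.solve(G.T, U.T).T


def save_model(result: EmbeddingResult, path: str) -> None:
    """Serialize U, Q, trace and config to a single ``.npz`` archive."""
    cfg = result.config
    import json

    cfg_json = "" if cfg is None else json.dumps(
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in vars(cfg).items()}
    )
    np.savez(
        path,
        U=result.U,
        Q=result.Q,
        objective_trace=np.asarray(result.objective_trace),
        n_iter=result.n_iter,
        converged=result.converged,
        config_json=np.array(cfg_json),
    )
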