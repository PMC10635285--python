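"""kNN graphs, graph Laplacians, filtrations, and the accumulated persistent Laplacian.

Two filtration constructions are provided over a point cloud of N cells:

* **distance filtration** — sweep a threshold over the (negated) Gaussian edge
  weights of a kNN graph, in the spirit of a Vietoris–Rips complex restricted
  to the kNN edge support.  Step t keeps the edges whose Laplacian entry
  ``l_ij = -W_ij`` satisfies ``l_ij <= (t/p)·(l_max-l_min) + l_min``, so the
  strongest (closest) edges enter first and the edge sets grow with t.
* **kNN filtration** — step k is the unweighted Laplacian of the
  union-symmetrized k-nearest-neighbor graph, k = 1…p.  No kernel scale or
  distance threshold is involved, which makes the sequence of connectivities
  scale-free.

Each step yields a 0-order graph Laplacian ``L^t`` (off-diagonal −1 on edges,
diagonal = vertex degree).  The **accumulated persistent Laplacian**
``PL = Σ_t ζ_t L^t`` consolidates the sequence into a single positive
semidefinite regularizer; the kernel dimension of any single ``L^t`` is the
Betti-0 number (connected-component count) of that step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csr_matrix
from scipy.spatial.distance import squareform, pdist

DEFAULT_K = 15
DEFAULT_P_KNN = 8
DEFAULT_P_DISTANCE = 7


@dataclass
class NeighborGraph:
    """Gaussian-weighted kNN graph: adjacency W, degrees, Laplacian L = D − W."""

    W: np.ndarray
    degree: np.ndarray
    L: np.ndarray
    k: int
    eta: float


@dataclass
class FiltrationSequence:
    """Ordered nested sequence of unweighted graph Laplacians L^1 … L^p."""

    laplacians: list[np.ndarray]
    mode: str  # "distance" or "knn"
    lmin: float | None = None
    lmax: float | None = None
    d: float | None = None

    @property
    def p(self) -> int:
        return len(self.laplacians)

    def edge_sets(self) -> list[set[tuple[int, int]]]:
        """Edge set (i < j pairs with entry −1) at each step."""
        out = []
        for L in self.laplacians:
            i, j = np.nonzero(np.triu(L, 1))
            out.append(set(zip(i.tolist(), j.tolist())))
        return out


@dataclass
class AccumulatedLaplacian:
    """ζ-weighted sum PL = Σ_t ζ_t L^t of a filtration sequence."""

    PL: np.ndarray
    zeta: np.ndarray


def _pairwise_sq(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    return squareform(pdist(points, metric="sqeuclidean"))


def knn_index(points: np.ndarray, k: int, metric: str = "euclidean") -> list[list[int]]:
    """k nearest neighbors of each point, self excluded.

    Distance ties are broken toward the smaller point index, so the result is
    deterministic.  Returns a list of k-lists of neighbor indices.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    d2 = _pairwise_sq(points)
    n = d2.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} must satisfy 1 <= k <= N-1 = {n - 1}")
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(n)
    out = []
    for i in range(n):
        # lexsort: primary key distance, secondary key index
        order = np.lexsort((idx, d2[i]))
        out.append(order[:k].tolist())
    return out


def _union_adjacency(neighbors: list[list[int]]) -> np.ndarray:
    """Boolean union-symmetrized adjacency from per-point neighbor lists."""
    n = len(neighbors)
    A = np.zeros((n, n), dtype=bool)
    for i, nbrs in enumerate(neighbors):
        A[i, nbrs] = True
    return A | A.T


def _unweighted_laplacian(A: np.ndarray) -> np.ndarray:
    L = -A.astype(float)
    np.fill_diagonal(L, 0.0)
    np.fill_diagonal(L, -L.sum(axis=1))
    return L


def gaussian_adjacency(
    points: np.ndarray, k: int = DEFAULT_K, eta: float | str = "auto"
) -> NeighborGraph:
    """Gaussian-kernel weighted adjacency on the union-kNN edge set.

    ``W_ij = exp(-‖x_i − x_j‖² / η)`` when i and j are kNN-linked (in either
    direction), 0 otherwise.  ``eta='auto'`` sets η to the mean squared
    distance to the k-th nearest neighbor — a per-dataset bandwidth that keeps
    typical edge weights well inside (0, 1).
    """
    d2 = _pairwise_sq(points)
    n = d2.shape[0]
    neighbors = knn_index(points, k)
    if eta == "auto":
        kth = np.array([d2[i, nbrs[-1]] for i, nbrs in enumerate(neighbors)])
        eta_val = float(kth.mean())
        if eta_val == 0:
            eta_val = 1.0  # all points coincident
    else:
        eta_val = float(eta)
        if eta_val <= 0:
            raise ValueError("eta must be positive")
    A = _union_adjacency(neighbors)
    W = np.where(A, np.exp(-d2 / eta_val), 0.0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2  # exact symmetry against FP noise
    degree = W.sum(axis=1)
    L = np.diag(degree) - W
    return NeighborGraph(W=W, degree=degree, L=L, k=k, eta=eta_val)


def graph_from_weights(W: np.ndarray, k: int | None = None) -> NeighborGraph:
    """Wrap an explicit symmetric weight matrix as a NeighborGraph."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    degree = W.sum(axis=1)
    return NeighborGraph(
        W=W, degree=degree, L=np.diag(degree) - W,
        k=k if k is not None else W.shape[0] - 1, eta=float("nan"),
    )


def distance_filtration(
    graph: NeighborGraph, p: int = DEFAULT_P_DISTANCE, *, inverted: bool = False
) -> FiltrationSequence:
    """Threshold sweep over the supported entries of the weighted Laplacian.

    The off-diagonal Laplacian entries on supported edges are
    ``l_ij = -W_ij < 0``; with ``l_min``/``l_max`` their extremes and
    ``d = l_max - l_min``, step t contains edge (i,j) iff
    ``l_ij <= (t/p)·d + l_min``.  Strong edges (large W, very negative l)
    therefore appear first and the complexes are nested increasing; at t = p
    the full supported edge set is present.  ``inverted=True`` inverts the
    comparison (edge present iff ``l_ij`` is *above* threshold), yielding a
    shrinking sequence instead.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    W = graph.W
    mask = np.triu(W, 1) > 0
    if not mask.any():
        raise ValueError("graph has no edges")
    lvals = -W[mask | mask.T]
    lmin, lmax = float(lvals.min()), float(lvals.max())
    d = lmax - lmin
    supported = (W > 0)
    lmat = -W
    laps = []
    for t in range(1, p + 1):
        thresh = (t / p) * d + lmin
        if inverted:
            present = supported & (lmat > thresh + 1e-12)
        else:
            present = supported & (lmat <= thresh + 1e-12)
        laps.append(_unweighted_laplacian(present))
    return FiltrationSequence(laps, mode="distance", lmin=lmin, lmax=lmax, d=d)


def knn_filtration(points: np.ndarray, p: int = DEFAULT_P_KNN) -> FiltrationSequence:
    """Neighbor-count sweep: step k is the union-symmetrized k-NN graph Laplacian."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0] if pts.ndim > 1 else pts.shape[0]
    if not 1 <= p <= n - 1:
        raise ValueError(f"p={p} must satisfy 1 <= p <= N-1 = {n - 1}")
    d2 = _pairwise_sq(pts)
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(n)
    orders = [np.lexsort((idx, d2[i])) for i in range(n)]
    laps = []
    for k in range(1, p + 1):
        A = _union_adjacency([orders[i][:k].tolist() for i in range(n)])
        laps.append(_unweighted_laplacian(A))
    return FiltrationSequence(laps, mode="knn")


def accumulate(
    filtration: FiltrationSequence, zeta: np.ndarray
) -> AccumulatedLaplacian:
    """Weighted sum PL = Σ_t ζ_t L^t; all ζ_t must be non-negative."""
    zeta = np.asarray(zeta, dtype=float)
    if zeta.shape != (filtration.p,):
        raise ValueError(
            f"zeta has length {zeta.size}, filtration has p={filtration.p} steps"
        )
    if np.any(zeta < 0):
        raise ValueError("zeta weights must be non-negative")
    if np.all(zeta == 0):
        import warnings

        warnings.warn("all-zero zeta: accumulated Laplacian is the zero matrix",
                      stacklevel=2)
    PL = sum(z * L for z, L in zip(zeta, filtration.laplacians))
    if np.isscalar(PL):  # p==0 cannot happen, but keep the type honest
        PL = np.zeros_like(filtration.laplacians[0])
    return AccumulatedLaplacian(PL=np.asarray(PL), zeta=zeta)


def reciprocal_zeta(p: int) -> np.ndarray:
    """The universal weighting ζ_t = 1/t, t = 1…p."""
    return 1.0 / np.arange(1, p + 1)


def betti0(laplacian: np.ndarray, rtol: float = 1e-8) -> int:
    """Connected-component count = kernel dimension of a graph Laplacian.

    Eigenvalues below ``rtol · max(1, λ_max)`` are counted as zero.
    """
    L = np.asarray(laplacian, dtype=float)
    if not np.allclose(L, L.T, atol=1e-10):
        raise ValueError("betti0 requires a symmetric matrix")
    eig = np.linalg.eigvalsh(L)
    lam_max = eig[-1] if eig.size else 0.0
    return int(np.sum(eig < rtol * max(1.0, lam_max)))


def save_filtration(
    filtration: FiltrationSequence,
    out_dir: str | Path,
    *,
    zeta: np.ndarray | None = None,
    eta: float | None = None,
    k: int | None = None,
) -> None:
    """Serialize each L^t to Matrix Market plus a JSON sidecar of parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, L in enumerate(filtration.laplacians, start=1):
        mmwrite(str(out / f"laplacian_{t:02d}.mtx"), csr_matrix(L))
    sidecar = {
        "mode": filtration.mode,
        "p": filtration.p,
        "lmin": filtration.lmin,
        "lmax": filtration.lmax,
        "d": filtration.d,
        "zeta": None if zeta is None else np.asarray(zeta).tolist(),
        "eta": eta,
        "k": k,
    }
    (out / "filtration.json").write_text(json.dumps(sidecar, indent=2) + "\n")
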