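"""Synthetic scRNA-seq-like data and deterministic toy geometries.

The count generator emulates the two properties of single-cell expression
matrices the models are designed around — cluster structure over cells and
dropout-induced sparsity — with a log-normal count model: per class, the
informative genes get class-specific log-means drawn once from a Gaussian
whose spread (in units of the within-cluster log-sd, fixed at 1) is the
``cluster_separation``; per-cell log-expression adds unit Gaussian noise,
counts are ``round(exp(·))``, dropout zeroes entries independently, and a
fraction of cells is scaled ×20 to act as magnitude outliers.

It makes no attempt to match real library-size or gene-detection
distributions; it exists so every pipeline stage is testable without
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_filtration import NeighborGraph, graph_from_weights
from .preprocess_io import ExpressionMatrix

OUTLIER_SCALE = 20.0


@dataclass
class SyntheticSpec:
    """Generator parameters; all randomness flows from ``seed``."""

    n_classes: int = 3
    cells_per_class: int = 100
    n_genes: int = 1000
    n_informative_genes: int | None = None  # default: 10% of genes
    cluster_separation: float = 5.0  # between-class spread / within-class sd
    dropout_rate: float = 0.4
    outlier_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.cells_per_class, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        if self.n_informative_genes is None:
            self.n_informative_genes = max(1, self.n_genes // 10)
        if not 0 < self.n_informative_genes <= self.n_genes:
            raise ValueError("n_informative_genes out of range")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")


def simulate_counts(spec: SyntheticSpec) -> ExpressionMatrix:
    """Generate a labeled genes-by-cells count matrix per the spec.

    Deterministic given ``spec.seed``; label proportions exactly match
    ``cells_per_class``.
    """
    rng = np.random.default_rng(spec.seed)
    m, n_cls, cpc = spec.n_genes, spec.n_classes, spec.cells_per_class
    n = n_cls * cpc
    sigma = 1.0  # within-cluster sd in log space

    base_mu = rng.normal(0.0, 1.0, size=m)
    mu = np.tile(base_mu[:, None], (1, n_cls))
    info = rng.choice(m, size=spec.n_informative_genes, replace=False)
    mu[info, :] = base_mu[info, None] + rng.normal(
        0.0, spec.cluster_separation * sigma, size=(spec.n_informative_genes, n_cls)
    )

    labels = [f"class_{c}" for c in range(n_cls) for _ in range(cpc)]
    cls_idx = np.repeat(np.arange(n_cls), cpc)
    logx = mu[:, cls_idx] + rng.normal(0.0, sigma, size=(m, n))
    counts = np.round(np.exp(logx))

    if spec.dropout_rate > 0:
        counts *= rng.random((m, n)) >= spec.dropout_rate
    if spec.outlier_frac > 0:
        n_out = int(round(spec.outlier_frac * n))
        out_idx = rng.choice(n, size=n_out, replace=False)
        counts[:, out_idx] *= OUTLIER_SCALE

    gene_ids = [f"gene_{i}" for i in range(m)]
    cell_ids = [f"cell_{j}" for j in range(n)]
    return ExpressionMatrix(counts, gene_ids, cell_ids, labels,
                            meta={"synthetic_spec": vars(spec).copy()})


def toy_geometries(name: str):
    """Deterministic fixtures backing the worked graph examples.

    ``line4``       — 1-D points {0, 1, 3, 7} as a (4, 1) array.
    ``two_blocks``  — Laplacian of the disjoint union K2 ⊕ K3 (5 nodes).
    ``three_weights`` — 3-node :class:`NeighborGraph` with edge weights
    {0.9, 0.5, 0.2}.
    """
    if name == "line4":
        return np.array([[0.0], [1.0], [3.0], [7.0]])
    if name == "two_blocks":
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = 1.0  # K2 on {0,1}
        for i in (2, 3, 4):  # K3 on {2,3,4}
            for j in (2, 3, 4):
                if i != j:
                    A[i, j] = 1.0
        L = np.diag(A.sum(axis=1)) - A
        return L
    if name == "three_weights":
        W = np.array(
            [
                [0.0, 0.9, 0.5],
                [0.9, 0.0, 0.2],
                [0.5, 0.2, 0.0],
            ]
        )
        return graph_from_weights(W, k=2)
    raise ValueError(f"unknown toy geometry {name!r}")
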