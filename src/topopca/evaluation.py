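"""Benchmarking protocols: k-means clustering evaluation, kNN classification
across subspace dimensions, and the ζ/γ hyper-parameter search schemes.

The clustering protocol reduces the data to as many dimensions as there are
classes, then scores k-means (k-means++ seeding with many restarts) against
the provided labels by ARI and NMI, averaged over repeated runs.  The
classification protocol fits the reduction on a stratified training split,
projects held-out cells into the learned basis, and scores a majority-vote
kNN classifier by the macro metrics, averaged over repeated splits and a grid
of subspace dimensions.

Three ζ-search schemes differ in their combinatorial budget for p filtration
steps and a γ grid of size G: the *full* scheme tries every ζ_t in
{1, 1/2, …, 1/p, 0} ((p+1)^p·G combinations); the *limited* scheme restricts
to m explicit combinations of three connectivity scales (m·(p+1)³·G); the
*knn* scheme weights each scale as important/unimportant, ζ_t ∈ {0, 1}
(2^p·G).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .metrics import ari, macro_classification, nmi
from .models import EmbeddingResult, ModelConfig, fit, transform
from .preprocess_io import ExpressionMatrix

DEFAULT_DIMS = tuple(list(range(100, 0, -10)) + [1])


@dataclass
class ClusterEvalReport:
    method: str
    ari_runs: list[float]
    nmi_runs: list[float]
    mean_ari: float
    mean_nmi: float
    config: ModelConfig
    n_runs: int
    n_init: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean_ari": self.mean_ari,
            "mean_nmi": self.mean_nmi,
            "ari_runs": self.ari_runs,
            "nmi_runs": self.nmi_runs,
            "n_runs": self.n_runs,
            "n_init": self.n_init,
            "seed": self.seed,
        }


@dataclass
class ClassifyEvalReport:
    method: str
    per_dimension: dict  # m -> {acc, macro_pre, macro_rec, macro_f1}
    grand_means: dict
    dims: list[int]
    seed: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_dimension": {str(k): v for k, v in self.per_dimension.items()},
            "grand_means": self.grand_means,
            "dims": self.dims,
            "seed": self.seed,
        }


@dataclass
class GridSpec:
    """Finite ζ/γ search grid for one of the three schemes."""

    scheme: str  # full | limited | knn
    p: int
    gamma_grid: list[float] = field(default_factory=lambda: [1.0])
    scale_combos: list[tuple[int, ...]] | None = None  # limited scheme only

    def zeta_candidates(self) -> list[np.ndarray]:
        p = self.p
        if self.scheme == "full":
            values = [1.0 / t for t in range(1, p + 1)] + [0.0]
            return [np.array(c) for c in itertools.product(values, repeat=p)]
        if self.scheme == "knn":
            return [np.array(c, dtype=float)
                    for c in itertools.product((0.0, 1.0), repeat=p)]
        if self.scheme == "limited":
            combos = self.scale_combos or default_scale_combos(p)
            values = [1.0 / t for t in range(1, p + 1)] + [0.0]
            out = []
            for combo in combos:
                if len(combo) != 3:
                    raise ValueError("limited scheme needs 3-scale combinations")
                for triple in itertools.product(values, repeat=3):
                    z = np.zeros(p)
                    for scale, v in zip(combo, triple):
                        z[scale] = v
                    out.append(z)
            return out
        raise ValueError(f"unknown scheme {self.scheme!r}")


def default_scale_combos(p: int, m_combos: int = 3) -> list[tuple[int, ...]]:
    """Default long/middle/close connectivity-scale triples (0-based steps)."""
    if p < 3:
        raise ValueError("limited scheme needs p >= 3")
    combos = [
        (0, (p - 1) // 2, p - 1),  # close / middle / long range
        (0, 1, 2),  # close range block
        (p - 3, p - 2, p - 1),  # long range block
    ]
    return combos[:m_combos]


def count_param_combinations(
    scheme: str, p: int, m_combos: int = 3, gamma_grid_size: int = 1
) -> int:
    """Number of configurations each search scheme evaluates."""
    if p < 1 or gamma_grid_size < 1:
        raise ValueError("p and gamma_grid_size must be >= 1")
    if scheme == "full":
        return (p + 1) ** p * gamma_grid_size
    if scheme == "limited":
        return m_combos * (p + 1) ** 3 * gamma_grid_size
    if scheme == "knn":
        return 2**p * gamma_grid_size
    raise ValueError(f"unknown scheme {scheme!r}")


def default_gamma_grid(
    low_exp: int = -10, high_exp: int = 10, per_decade_pair: int = 5
) -> list[float]:
    """Log-uniform γ grid spanning 10^low to 10^high."""
    n = (high_exp - low_exp) // 2 * per_decade_pair + 1
    return list(np.logspace(low_exp, high_exp, n))


def _kmeans_labels(Q: np.ndarray, n_clusters: int, n_init: int, seed: int):
    km = KMeans(n_clusters=n_clusters, n_init=n_init, init="k-means++",
                random_state=seed)
    return km.fit_predict(Q)


def cluster_eval(
    xm: ExpressionMatrix,
    config: ModelConfig,
    n_runs: int = 30,
    n_init: int = 150,
    seed: int = 0,
    *,
    fitted: EmbeddingResult | None = None,
) -> ClusterEvalReport:
    """Fit once, k-means ``n_runs`` times with distinct seeds, score ARI/NMI.

    The embedding dimension is forced to the number of distinct labels.  Run
    seeds are ``seed + run`` (fixed counter), so reports are reproducible.
    """
    if xm.labels is None:
        raise ValueError("cluster_eval requires labels")
    classes = list(dict.fromkeys(xm.labels))
    n_clusters = len(classes)
    if xm.n_cells < n_clusters:
        raise ValueError("fewer cells than clusters")
    config = replace(config, m=n_clusters)
    result = fitted if fitted is not None else fit(xm.values, config)
    ari_runs, nmi_runs = [], []
    for run in range(n_runs):
        pred = _kmeans_labels(result.Q, n_clusters, n_init, seed + run)
        ari_runs.append(ari(xm.labels, pred.tolist()))
        nmi_runs.append(nmi(xm.labels, pred.tolist()))
    return ClusterEvalReport(
        method=config.method_name,
        ari_runs=ari_runs,
        nmi_runs=nmi_runs,
        mean_ari=float(np.mean(ari_runs)),
        mean_nmi=float(np.mean(nmi_runs)),
        config=config,
        n_runs=n_runs,
        n_init=n_init,
        seed=seed,
    )


def _stratified_split(labels, train_frac: float, rng: np.random.Generator):
    labels = np.asarray(labels, dtype=object)
    train_idx, test_idx = [], []
    for c in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        n_train = max(1, int(round(train_frac * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def _knn_predict(train_pts, train_labels, test_pts, k: int):
    D = cdist(test_pts, train_pts)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    preds = []
    train_labels = list(train_labels)
    for row in order:
        votes: dict = {}
        for idx in row:
            lab = train_labels[idx]
            votes[lab] = votes.get(lab, 0) + 1
        best = max(votes.values())
        # ties broken by nearest neighbor order
        for idx in row:
            if votes[train_labels[idx]] == best:
                preds.append(train_labels[idx])
                break
    return preds


def classify_eval(
    xm: ExpressionMatrix,
    config: ModelConfig,
    dims: list[int] | None = None,
    train_frac: float = 0.6,
    n_folds: int = 5,
    n_repeats: int = 5,
    knn_k: int = 5,
    seed: int = 0,
) -> ClassifyEvalReport:
    """kNN classification after dimensionality reduction, over a dimension grid.

    Per dimension m and per stratified train/test split (``n_folds`` splits ×
    ``n_repeats`` repeats): fit the reduction on training cells only, map both
    splits through :func:`transform` with the learned loadings, classify test
    cells by majority-vote kNN, and score the macro metrics.  Classes with
    fewer than ``n_folds`` members are dropped with a warning.
    """
    if xm.labels is None:
        raise ValueError("classify_eval requires labels")
    labels = np.asarray(xm.labels, dtype=object)
    counts = {c: int(np.sum(labels == c)) for c in dict.fromkeys(xm.labels)}
    small = [c for c, v in counts.items() if v < n_folds]
    values, labels_list = xm.values, list(xm.labels)
    if small:
        import warnings

        warnings.warn(f"dropping classes with < {n_folds} members: {small}",
                      stacklevel=2)
        keep = [j for j, lab in enumerate(labels_list) if lab not in small]
        values = values[:, keep]
        labels_list = [labels_list[j] for j in keep]
    M, N = values.shape
    if dims is None:
        dims = list(DEFAULT_DIMS)
    dims = sorted({min(m, N - 1, M) for m in dims}, reverse=True)
    dims = [m for m in dims if m >= 1]

    rng = np.random.default_rng(seed)
    per_dim: dict[int, dict[str, float]] = {}
    for m in dims:
        cfg = replace(config, m=m)
        accs = {"acc": [], "macro_pre": [], "macro_rec": [], "macro_f1": []}
        for _rep in range(n_repeats):
            for _fold in range(n_folds):
                tr, te = _stratified_split(labels_list, train_frac, rng)
                if len(tr) < m:
                    cfg = replace(cfg, m=len(tr))
                res = fit(values[:, tr], cfg)
                coords_tr = transform(res.U, values[:, tr])
                coords_te = transform(res.U, values[:, te])
                y_tr = [labels_list[j] for j in tr]
                y_te = [labels_list[j] for j in te]
                pred = _knn_predict(coords_tr, y_tr, coords_te, knn_k)
                scores = macro_classification(y_te, pred)
                for key in accs:
                    accs[key].append(scores[key])
        per_dim[m] = {k: float(np.mean(v)) for k, v in accs.items()}
    grand = {
        k: float(np.mean([per_dim[m][k] for m in dims]))
        for k in ("acc", "macro_pre", "macro_rec", "macro_f1")
    }
    return ClassifyEvalReport(
        method=config.method_name,
        per_dimension=per_dim,
        grand_means=grand,
        dims=dims,
        seed=seed,
    )


def zeta_grid_search(
    xm: ExpressionMatrix,
    base_config: ModelConfig,
    grid: GridSpec,
    objective_metric: str = "ari",
    seed: int = 0,
    search_n_runs: int = 5,
    final_n_runs: int = 30,
    n_init: int = 150,
):
    """Exhaustive ζ/γ search, scored by clustering agreement with the labels.

    Each grid point is evaluated with a reduced number of k-means runs
    (``search_n_runs``); the winner is re-scored at the full protocol.  Ties
    go to the smaller grid index.  Returns ``(best_config, best_report,
    leaderboard)`` where the leaderboard rows are
    ``(zeta, gamma, mean_score)`` in grid order.
    """
    if objective_metric not in ("ari", "nmi"):
        raise ValueError("objective_metric must be 'ari' or 'nmi'")
    zetas = grid.zeta_candidates()
    if not zetas or not grid.gamma_grid:
        raise ValueError("empty grid")
    leaderboard = []
    best_score, best_idx, best_cfg = -np.inf, -1, None
    idx = 0
    for zeta in zetas:
        for gamma in grid.gamma_grid:
            cfg = replace(base_config, zeta=zeta, gamma=float(gamma), p=grid.p)
            if np.all(zeta == 0):
                # zero regularizer: drop the Laplacian term instead of warning
                cfg = replace(cfg, gamma=0.0, zeta=None)
            report = cluster_eval(xm, cfg, n_runs=search_n_runs, n_init=n_init,
                                  seed=seed)
            score = report.mean_ari if objective_metric == "ari" else report.mean_nmi
            leaderboard.append(
                {"zeta": zeta.tolist(), "gamma": float(gamma), "score": score}
            )
            if score > best_score:
                best_score, best_idx, best_cfg = score, idx, cfg
            idx += 1
    final = cluster_eval(xm, best_cfg, n_runs=final_n_runs, n_init=n_init, seed=seed)
    return best_cfg, final, leaderboard
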