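"""Evaluation statistics: ARI, NMI, macro classification metrics, RS scores.

ARI and NMI are computed from the r×s contingency table of two labelings.
The macro classification metrics average one-vs-rest precision and recall
over the classes of the true labeling, and the macro-F1 is the harmonic mean
of the macro averages (not the mean of per-class F1 scores).

Residue–similarity (RS) scores characterize multiclass separation without a
2-D embedding: per sample, the residue R_i is the class-normalized sum of
distances to all points *outside* its class, and the similarity S_i the
average of ``1 − d/d_max`` over points *inside* its class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, log
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class ContingencyTable:
    """Overlap counts a_ij between two labelings, with marginals."""

    a: np.ndarray  # r x s integer matrix
    row_sums: np.ndarray  # q_i
    col_sums: np.ndarray  # p_j
    n: int


def contingency(labels_true, labels_pred) -> ContingencyTable:
    lt, lp = list(labels_true), list(labels_pred)
    if len(lt) != len(lp):
        raise ValueError(f"label vectors differ in length: {len(lt)} vs {len(lp)}")
    if len(lt) < 2:
        raise ValueError("need at least 2 samples")
    t_classes = {c: i for i, c in enumerate(dict.fromkeys(lt))}
    p_classes = {c: j for j, c in enumerate(dict.fromkeys(lp))}
    a = np.zeros((len(t_classes), len(p_classes)), dtype=np.int64)
    for t, p in zip(lt, lp):
        a[t_classes[t], p_classes[p]] += 1
    return ContingencyTable(
        a=a, row_sums=a.sum(axis=1), col_sums=a.sum(axis=0), n=len(lt)
    )


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index from the binomial-coefficient contingency form.

    ARI = [Σ C(a_ij,2) − Σ C(q_i,2)·Σ C(p_j,2)/C(n,2)]
          / [½(Σ C(q_i,2)+Σ C(p_j,2)) − Σ C(q_i,2)·Σ C(p_j,2)/C(n,2)]
    """
    ct = contingency(labels_true, labels_pred)
    sum_ij = sum(comb(int(v), 2) for v in ct.a.ravel())
    sum_q = sum(comb(int(v), 2) for v in ct.row_sums)
    sum_p = sum(comb(int(v), 2) for v in ct.col_sums)
    n2 = comb(ct.n, 2)
    expected = sum_q * sum_p / n2
    denom = 0.5 * (sum_q + sum_p) - expected
    if denom == 0:
        # both partitions trivial (all-singletons or single-class): agreement
        return 1.0
    return (sum_ij - expected) / denom


def _entropy(counts: np.ndarray, n: int) -> float:
    probs = counts[counts > 0] / n
    return float(-np.sum(probs * np.log(probs)))


def nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information, MI / ((E(T)+E(P))/2), natural logs.

    Conventions for degenerate partitions: both single-class → 1 (identical
    trivial splittings); exactly one trivial → 0.
    """
    ct = contingency(labels_true, labels_pred)
    h_t = _entropy(ct.row_sums, ct.n)
    h_p = _entropy(ct.col_sums, ct.n)
    if h_t == 0 and h_p == 0:
        return 1.0
    if h_t == 0 or h_p == 0:
        return 0.0
    mi = 0.0
    n = ct.n
    for i in range(ct.a.shape[0]):
        for j in range(ct.a.shape[1]):
            nij = ct.a[i, j]
            if nij > 0:
                mi += (nij / n) * log(n * nij / (ct.row_sums[i] * ct.col_sums[j]))
    return mi / ((h_t + h_p) / 2.0)


def macro_classification(y_true, y_pred) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 (one-vs-rest over true classes).

    Classes never predicted contribute precision 0.  Macro-F1 is the harmonic
    mean of macro-precision and macro-recall.
    """
    yt, yp = list(y_true), list(y_pred)
    if len(yt) != len(yp):
        raise ValueError("length mismatch")
    if not yt:
        raise ValueError("empty input")
    classes = list(dict.fromkeys(yt))
    precisions, recalls = [], []
    for c in classes:
        tp = sum(1 for t, p in zip(yt, yp) if t == c and p == c)
        fp = sum(1 for t, p in zip(yt, yp) if t != c and p == c)
        fn = sum(1 for t, p in zip(yt, yp) if t == c and p != c)
        precisions.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
    macro_pre = float(np.mean(precisions))
    macro_rec = float(np.mean(recalls))
    if macro_pre + macro_rec > 0:
        macro_f1 = 2 * macro_pre * macro_rec / (macro_pre + macro_rec)
    else:
        macro_f1 = 0.0
    acc = sum(1 for t, p in zip(yt, yp) if t == p) / len(yt)
    return {
        "acc": acc,
        "macro_pre": macro_pre,
        "macro_rec": macro_rec,
        "macro_f1": macro_f1,
    }


@dataclass
class RSResult:
    """Per-sample residue (R) and similarity (S) scores."""

    R: np.ndarray
    S: np.ndarray
    R_max: dict  # per-class maximum of the unnormalized residue sums
    d_max: float
    labels: list


def rs_scores(
    points: np.ndarray,
    labels,
    *,
    include_self: bool = True,
    global_rmax: bool = False,
) -> RSResult:
    """Residue and similarity scores over a labeled point set.

    R_i = (1/R_max) Σ_{j ∉ class(i)} ‖x_i − x_j‖ with R_max the per-class
    maximum of the raw sums (or the global maximum with ``global_rmax``);
    S_i = (1/|C_l|) Σ_{j ∈ class(i)} (1 − ‖x_i − x_j‖ / d_max), the sum
    including the self term by default.  Euclidean distances throughout.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = list(labels)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    D = squareform(pdist(pts))
    d_max = float(D.max())
    lab_arr = np.asarray(labels, dtype=object)
    classes = list(dict.fromkeys(labels))

    raw_R = np.zeros(n)
    S = np.zeros(n)
    for i in range(n):
        same = lab_arr == labels[i]
        if not include_self:
            same_idx = np.flatnonzero(same)
            same_idx = same_idx[same_idx != i]
        else:
            same_idx = np.flatnonzero(same)
        other_idx = np.flatnonzero(~same)
        raw_R[i] = D[i, other_idx].sum()
        if len(same_idx) == 0:
            S[i] = 1.0
        elif d_max == 0:
            S[i] = 1.0
        else:
            S[i] = float(np.mean(1.0 - D[i, same_idx] / d_max))

    R = np.full(n, np.nan)
    R_max: dict = {}
    if len(classes) < 2:
        warnings.warn("single class: residue scores undefined (NaN)", stacklevel=2)
    else:
        if global_rmax:
            gmax = raw_R.max()
        for c in classes:
            idx = np.flatnonzero(lab_arr == c)
            rmax = float(raw_R[idx].max()) if not global_rmax else float(gmax)
            R_max[c] = rmax
            if rmax > 0:
                R[idx] = raw_R[idx] / rmax
            else:
                R[idx] = 0.0
    return RSResult(R=R, S=S, R_max=R_max, d_max=d_max, labels=labels)


def rs_to_csv(result: RSResult, cell_ids, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "class": result.labels,
            "R": result.R,
            "S": result.S,
        }
    ).to_csv(path, index=False)
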