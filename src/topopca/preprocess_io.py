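"""Expression-matrix I/O and preprocessing.

The in-memory container is :class:`ExpressionMatrix`: a dense genes-by-cells
matrix ``X ∈ R^{M×N}`` with gene and cell identifiers and optional per-cell
class labels.  The preprocessing chain applied to raw counts before any
model fit is, in order:

1. elementwise ``log1p`` transform,
2. flooring: entries below a small threshold are set to zero,
3. low-variance gene removal (the lowest-variance fraction is dropped),
4. removal of cells whose class has too few members.

z-scoring (per-gene demean / unit variance) is a separate step because the
non-negative matrix factorization comparators in typical pipelines skip it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix


class DegenerateInputError(ValueError):
    """All rows (genes) were removed by a filtering step."""


@dataclass
class ExpressionMatrix:
    """Genes-by-cells expression matrix with identifiers and optional labels.

    Attributes
    ----------
    values : (M, N) ndarray
        Expression values; genes are rows, cells are columns.
    gene_ids : list of str, length M
    cell_ids : list of str, length N
    labels : list of str of length N, or None
        Per-cell class labels.
    meta : dict
        Free-form provenance (preprocessing counts, flags).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x cells)")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} cells")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.gene_ids),
            list(self.cell_ids),
            None if self.labels is None else list(self.labels),
            dict(self.meta),
        )


def load_expression(
    path: str | Path,
    format: str | None = None,
    *,
    cells_in: str = "columns",
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV, or Matrix Market MTX.

    CSV/TSV layout: header row of cell ids, first column of gene ids.
    MTX: companion ``genes.txt`` / ``barcodes.txt`` files next to the matrix
    (one id per line); synthetic ids are generated when absent.

    ``cells_in`` declares the on-disk orientation ("columns" or "rows"); the
    returned matrix always has genes as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format not in ("csv", "tsv", "mtx"):
        raise ValueError(f"unknown format {format!r}")
    if cells_in not in ("rows", "columns"):
        raise ValueError("cells_in must be 'rows' or 'columns'")

    if format == "mtx":
        raw = mmread(str(path))
        # coordinate-format files come back sparse, array-format dense
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.txt"
        barcodes_file = (
            Path(barcodes_file) if barcodes_file else path.parent / "barcodes.txt"
        )
        if cells_in == "rows":
            mat = mat.T
        m, n = mat.shape
        if genes_file.exists():
            gene_ids = genes_file.read_text().split()
        else:
            gene_ids = [f"gene_{i}" for i in range(m)]
        if barcodes_file.exists():
            cell_ids = barcodes_file.read_text().split()
        else:
            cell_ids = [f"cell_{j}" for j in range(n)]
        if len(gene_ids) != m:
            raise ValueError(
                f"gene id file has {len(gene_ids)} entries for {m} matrix rows"
            )
        if len(cell_ids) != n:
            raise ValueError(
                f"cell id file has {len(cell_ids)} entries for {n} matrix columns"
            )
    else:
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, na_filter=False)
            mat = df.to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        if cells_in == "rows":
            df = df.T
            mat = mat.T
            gene_ids = [str(c) for c in df.index]
            cell_ids = [str(c) for c in df.columns]
        else:
            gene_ids = [str(i) for i in df.index]
            cell_ids = [str(c) for c in df.columns]
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{path} contains non-finite values")
    return ExpressionMatrix(mat, gene_ids, cell_ids)


def save_expression(
    xm: ExpressionMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a matrix to CSV/TSV (gene ids as index, cell ids as header) or MTX
    (with ``genes.txt``/``barcodes.txt`` siblings)."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "mtx":
        mmwrite(str(path), csr_matrix(xm.values))
        (path.parent / "genes.txt").write_text("\n".join(xm.gene_ids) + "\n")
        (path.parent / "barcodes.txt").write_text("\n".join(xm.cell_ids) + "\n")
    else:
        sep = "," if format == "csv" else "\t"
        pd.DataFrame(xm.values, index=xm.gene_ids, columns=xm.cell_ids).to_csv(
            path, sep=sep
        )


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a ``cell_id,label`` CSV into a mapping."""
    df = pd.read_csv(path, dtype=str)
    if not {"cell_id", "label"}.issubset(df.columns):
        raise ValueError("labels file needs columns cell_id,label")
    return dict(zip(df["cell_id"], df["label"]))


def attach_labels(xm: ExpressionMatrix, labels: dict[str, str]) -> ExpressionMatrix:
    missing = [c for c in xm.cell_ids if c not in labels]
    if missing:
        raise ValueError(f"{len(missing)} cells missing labels, e.g. {missing[:3]}")
    out = xm.copy()
    out.labels = [labels[c] for c in xm.cell_ids]
    return out


def preprocess(
    xm: ExpressionMatrix,
    variance_drop_frac: float = 0.20,
    min_class_size: int = 15,
    floor: float = 1e-6,
) -> ExpressionMatrix:
    """Apply the standard preprocessing chain to a raw count matrix.

    Steps, in fixed order: (1) log1p; (2) entries below ``floor`` set to 0;
    (3) drop the ``floor(variance_drop_frac * M)`` lowest-variance genes
    (ties keep the smaller row index); (4) drop cells of classes with fewer
    than ``min_class_size`` members (skipped with a warning when unlabeled).

    The returned matrix's ``meta['preprocess']`` records counts removed at
    each step.
    """
    if not 0 <= variance_drop_frac <= 1:
        raise ValueError("variance_drop_frac must be in [0, 1]")
    if np.any(xm.values < 0):
        raise ValueError("preprocess expects non-negative values")
    vals = np.log1p(xm.values)
    n_floored = int(np.sum((vals < floor) & (vals != 0)))
    vals = np.where(vals < floor, 0.0, vals)

    m = vals.shape[0]
    n_drop = int(np.floor(variance_drop_frac * m))
    variances = vals.var(axis=1)
    # stable sort: ties at the boundary drop the smaller row index first
    order = np.argsort(variances, kind="stable")
    drop_idx = set(order[:n_drop].tolist())
    keep = [i for i in range(m) if i not in drop_idx]
    if not keep:
        raise DegenerateInputError("variance filtering removed every gene")
    vals = vals[keep, :]
    gene_ids = [xm.gene_ids[i] for i in keep]

    cell_ids = list(xm.cell_ids)
    labels = None if xm.labels is None else list(xm.labels)
    n_cells_dropped = 0
    classes_dropped: list[str] = []
    if min_class_size > 0:
        if labels is None:
            warnings.warn(
                "no labels present; small-class filtering skipped", stacklevel=2
            )
        else:
            counts = pd.Series(labels).value_counts()
            small = set(counts[counts < min_class_size].index)
            if small:
                keep_cells = [j for j, lab in enumerate(labels) if lab not in small]
                n_cells_dropped = len(labels) - len(keep_cells)
                classes_dropped = sorted(small)
                vals = vals[:, keep_cells]
                cell_ids = [cell_ids[j] for j in keep_cells]
                labels = [labels[j] for j in keep_cells]

    out = ExpressionMatrix(vals, gene_ids, cell_ids, labels, dict(xm.meta))
    out.meta["preprocess"] = {
        "n_floored": n_floored,
        "n_genes_dropped": n_drop,
        "n_cells_dropped": n_cells_dropped,
        "classes_dropped": classes_dropped,
        "variance_drop_frac": variance_drop_frac,
        "min_class_size": min_class_size,
        "floor": floor,
    }
    return out


def zscore(xm: ExpressionMatrix) -> ExpressionMatrix:
    """Demean each gene and scale to unit population standard deviation.

    Zero-variance genes are left at 0 and their indices recorded under
    ``meta['zscore_zero_variance_genes']``.  Idempotent within 1e-12.
    """
    vals = xm.values
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = xm.copy()
    out.values = (vals - mu) / safe_sd
    out.values[flat, :] = 0.0
    out.meta["zscore_zero_variance_genes"] = np.flatnonzero(flat).tolist()
    return out


def write_report(xm: ExpressionMatrix, path: str | Path) -> None:
    """Dump the preprocessing report (counts per step) as JSON."""
    Path(path).write_text(json.dumps(xm.meta.get("preprocess", {}), indent=2) + "\n")
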