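"""Matrix input/output, normalization, feature intersection, and the
query-side k-nearest-neighbor graph.

Matrices are cells x features.  Two on-disk dialects are supported:

* dense CSV/TSV — header row holds feature names, first column holds cell
  identifiers;
* MatrixMarket ``.mtx`` with plain-text ``.rownames`` / ``.colnames``
  sidecar files (one name per line).

Labels travel as a two-column TSV (``cell_id``, ``cell_type``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances


@dataclass
class ExpressionMatrix:
    """A cells x features expression matrix with names and optional labels.

    ``values`` holds nonnegative reals (raw counts, gene-activity scores,
    binarized peak accessibility, or normalized values).  ``labels``, when
    present, carries one cell-type string per cell (reference side only).
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_names: list[str]
    labels: list[str] | None = None

    def __post_init__(self):
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x features matrix")
        n, f = self.values.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_names = [str(g) for g in self.feature_names]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_names) != f:
            raise ValueError(f"{len(self.feature_names)} feature names for {f} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_names)) != f:
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError(f"{len(self.labels)} labels for {n} cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class NeighborGraph:
    """Per-query-cell ordered neighbor lists from PCA + exact kNN."""

    neighbor_indices: np.ndarray  # (n_query, k_eff) int
    k: int
    n_components: int

    def __post_init__(self):
        self.neighbor_indices = np.asarray(self.neighbor_indices, dtype=np.int64)
        n = self.neighbor_indices.shape[0]
        if np.any((self.neighbor_indices < 0) | (self.neighbor_indices >= n)):
            raise ValueError("neighbor index out of range")
        rows = np.arange(n)[:, None]
        if np.any(self.neighbor_indices == rows):
            raise ValueError("a cell appears in its own neighbor list")


# ----------------------------------------------------------------------
# Reading and writing
# ----------------------------------------------------------------------

def read_matrix(path: str, format: str = "dense_csv", labels_path: str | None = None) -> ExpressionMatrix:
    """Read an :class:`ExpressionMatrix` from disk.

    ``format`` is ``"dense_csv"`` (comma or tab separated, inferred) or
    ``"mtx_triplet"`` (``path`` names the ``.mtx`` file; ``path + ".rownames"``
    and ``path + ".colnames"`` must exist).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "dense_csv":
        sep = "\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = ExpressionMatrix(
            values=df.to_numpy(dtype=np.float64),
            cell_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
        )
    elif format == "mtx_triplet":
        rows_f, cols_f = path + ".rownames", path + ".colnames"
        for side in (rows_f, cols_f):
            if not os.path.exists(side):
                raise FileNotFoundError(side)
        values = np.asarray(scipy.io.mmread(path).todense())
        cell_ids = _read_names(rows_f)
        feature_names = _read_names(cols_f)
        if len(cell_ids) != values.shape[0] or len(feature_names) != values.shape[1]:
            raise ValueError(
                f"matrix is {values.shape} but sidecars name "
                f"{len(cell_ids)} rows and {len(feature_names)} columns"
            )
        mat = ExpressionMatrix(values=values, cell_ids=cell_ids, feature_names=feature_names)
    else:
        raise ValueError(f"unknown format {format!r}")
    if labels_path is not None:
        labels = read_labels(labels_path)
        mat.labels = [labels[c] for c in mat.cell_ids]
    return mat


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_matrix(mat: ExpressionMatrix, path: str, format: str = "dense_csv") -> None:
    """Write a matrix in one of the dialects :func:`read_matrix` accepts."""
    if format == "dense_csv":
        sep = "\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
        pd.DataFrame(mat.values, index=mat.cell_ids, columns=mat.feature_names).to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(path, sp.coo_matrix(mat.values))
        if not os.path.exists(path) and os.path.exists(path + ".mtx"):
            os.replace(path + ".mtx", path)  # mmwrite appends .mtx when absent
        with open(path + ".rownames", "w") as fh:
            fh.write("\n".join(mat.cell_ids) + "\n")
        with open(path + ".colnames", "w") as fh:
            fh.write("\n".join(mat.feature_names) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str) -> dict[str, str]:
    """Read a two-column (cell_id, cell_type) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id, cell_type")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(cell_ids: list[str], labels: list[str], path: str) -> None:
    pd.DataFrame({"cell_id": cell_ids, "cell_type": labels}).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Normalization and feature handling
# ----------------------------------------------------------------------

def log_normalize(x: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Total-count normalize each cell to ``scale`` and apply log1p.

    The standard single-cell recipe: each cell's values are divided by the
    cell's total, multiplied by ``scale``, then log(1 + .).  Cells with zero
    total pass through as all-zero.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if np.any(x.values < 0):
        raise ValueError("log_normalize requires nonnegative values")
    totals = x.values.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    out = np.log1p(x.values / safe * scale)
    return replace(x, values=out)


def intersect_features(ref: ExpressionMatrix, query: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common features, in identical order.

    The shared features keep the reference's ordering.
    """
    qset = set(query.feature_names)
    common = [g for g in ref.feature_names if g in qset]
    if not common:
        raise ValueError("reference and query share no features")
    ref_idx = [ref.feature_names.index(g) for g in common] if len(common) < ref.n_features else None
    q_pos = {g: i for i, g in enumerate(query.feature_names)}
    q_idx = [q_pos[g] for g in common]
    ref_out = replace(
        ref,
        values=ref.values[:, ref_idx] if ref_idx is not None else ref.values,
        feature_names=common,
    )
    query_out = replace(query, values=query.values[:, q_idx], feature_names=common)
    return ref_out, query_out


# ----------------------------------------------------------------------
# Neighborhood graph
# ----------------------------------------------------------------------

def build_knn_graph(query: ExpressionMatrix, n_components: int = 50, k: int = 15) -> NeighborGraph:
    """PCA then exact Euclidean k-nearest neighbors of the query cells.

    The query is log-normalized, reduced to
    ``min(n_components, n_query - 1, n_features)`` principal components with
    a deterministic full-SVD solver, and each cell's
    ``min(k, n_query - 1)`` nearest neighbors (self excluded) are found by
    exact pairwise distances.  Distance ties break by ascending cell index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = query.n_cells
    if n < 2:
        raise ValueError("need at least two query cells")
    x = log_normalize(query).values
    d = min(n_components, n - 1, query.n_features)
    if d < x.shape[1]:
        x = PCA(n_components=d, svd_solver="full").fit_transform(x)
    dist = pairwise_distances(x, metric="euclidean")
    np.fill_diagonal(dist, np.inf)
    k_eff = min(k, n - 1)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
    return NeighborGraph(neighbor_indices=order, k=k, n_components=d)
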