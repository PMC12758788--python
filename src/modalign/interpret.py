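"""Integrated-gradients attribution and determinant-feature extraction.

For each annotated query cell the contribution of every input feature to
the predicted class's pre-softmax score is estimated by integrated
gradients along the straight path from a baseline (all-zeros by default)
to the cell:

    IG_j(x) = (x_j - b_j) * (1/S) * sum_s dF/dx_j evaluated at
              b + (s - 0.5)/S * (x - b)          (midpoint Riemann sum)

which satisfies the completeness axiom sum_j IG_j -> F(x) - F(b) as the
number of steps S grows, exactly so for linear F.

Per cell, the 100 highest-attribution features are its determinant
features; per predicted cell type, the 50 features occurring most often in
its cells' determinant lists are the type's determinant features.  The key
gene hit rate (KGHR) of a type is the fraction of its determinant features
found in a curated marker list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .networks import Model
from .predict import UNKNOWN, PredictionResult

PER_CELL_TOP = 100
PER_TYPE_TOP = 50


@dataclass
class AttributionResult:
    attributions: np.ndarray   # (n, n_features)
    target_class: np.ndarray   # (n,) int
    baseline: np.ndarray       # (n_features,)
    n_steps: int


@dataclass
class DeterminantFeatures:
    per_cell_top: list[list[str]]
    per_type_top: dict[str, list[str]]
    per_type_frequency: dict[str, dict[str, float]]


def integrated_gradients(
    model: Model,
    x: np.ndarray,
    target: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 50,
) -> AttributionResult:
    """Midpoint-rule integrated gradients of the target-class logit."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dtype = np.dtype(model.config.dtype)
    x = np.asarray(x, dtype=dtype)
    target = np.asarray(target, dtype=np.int64)
    if baseline is None:
        baseline = np.zeros(x.shape[1], dtype=dtype)
    baseline = np.asarray(baseline, dtype=dtype)
    if baseline.shape != (x.shape[1],):
        raise ValueError("baseline width must match the input features")

    delta = x - baseline
    grad_sum = np.zeros_like(x, dtype=np.float64)
    rows = np.arange(x.shape[0])
    for s in range(n_steps):
        frac = (s + 0.5) / n_steps
        xt = Tensor((baseline + frac * delta).astype(dtype), requires_grad=True)
        logits = model.forward_logits(model.forward_embed(xt, training=False))
        logits[(rows, target)].sum().backward()
        grad_sum += xt.grad
    attributions = delta.astype(np.float64) * (grad_sum / n_steps)
    return AttributionResult(attributions=attributions, target_class=target, baseline=np.asarray(baseline, dtype=np.float64), n_steps=n_steps)


def logit_values(model: Model, x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Target-class pre-softmax scores (for completeness checks)."""
    dtype = np.dtype(model.config.dtype)
    logits = model.forward_logits(model.forward_embed(Tensor(np.asarray(x, dtype=dtype)), training=False)).data
    return logits[np.arange(x.shape[0]), np.asarray(target, dtype=np.int64)]


def determinant_features(
    attr: AttributionResult,
    predictions: PredictionResult,
    feature_names: list[str],
    per_cell_k: int = PER_CELL_TOP,
    per_type_k: int = PER_TYPE_TOP,
) -> DeterminantFeatures:
    """Rank features per cell, then aggregate per predicted type.

    Per cell: features sorted by descending attribution (ties by ascending
    feature index), top ``per_cell_k`` kept.  Per type (Unknown excluded):
    features ranked by occurrence frequency across the type's cells, ties
    by higher mean attribution then feature index; top ``per_type_k`` kept.
    """
    n, F = attr.attributions.shape
    if n != len(predictions.assigned_type):
        raise ValueError("attributions and predictions cover different cells")
    k_cell = min(per_cell_k, F)
    k_type = min(per_type_k, F)
    idx = np.arange(F)
    per_cell_idx = []
    for i in range(n):
        order = np.lexsort((idx, -attr.attributions[i]))[:k_cell]
        per_cell_idx.append(order)
    per_cell_top = [[feature_names[j] for j in order] for order in per_cell_idx]

    per_type_top: dict[str, list[str]] = {}
    per_type_frequency: dict[str, dict[str, float]] = {}
    types = sorted(set(predictions.assigned_type) - {UNKNOWN})
    assigned = np.array(predictions.assigned_type)
    for t in types:
        cells = np.flatnonzero(assigned == t)
        counts = np.zeros(F, dtype=np.int64)
        for i in cells:
            counts[per_cell_idx[i]] += 1
        freq = counts / len(cells)
        mean_attr = attr.attributions[cells].mean(axis=0)
        order = np.lexsort((idx, -mean_attr, -freq))[:k_type]
        per_type_top[t] = [feature_names[j] for j in order]
        per_type_frequency[t] = {feature_names[j]: float(freq[j]) for j in order}
    return DeterminantFeatures(per_cell_top=per_cell_top, per_type_top=per_type_top, per_type_frequency=per_type_frequency)


def kghr(determinant: dict[str, list[str]], markers: dict[str, list[str]]) -> dict[str, float]:
    """Key gene hit rate: |determinant ∩ markers| / |determinant| per type."""
    out: dict[str, float] = {}
    for t in determinant:
        if t not in markers:
            continue
        det = determinant[t]
        if not det:
            raise ValueError(f"type {t!r} has an empty determinant list")
        out[t] = len(set(det) & set(markers[t])) / len(det)
    return out


# ----------------------------------------------------------------------
# Table writers / readers
# ----------------------------------------------------------------------

def write_determinant_features(det: DeterminantFeatures, path: str) -> None:
    rows = []
    for t, feats in det.per_type_top.items():
        for rank, f in enumerate(feats, start=1):
            rows.append({"cell_type": t, "rank": rank, "feature": f, "frequency": det.per_type_frequency[t][f]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_kghr(scores: dict[str, float], path: str) -> None:
    pd.DataFrame({"cell_type": list(scores), "kghr": list(scores.values())}).to_csv(path, sep="\t", index=False)


def read_marker_lists(path: str) -> dict[str, list[str]]:
    """Two-column TSV (cell_type, feature) -> per-type marker lists."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("marker file needs two columns: cell_type, feature")
    out: dict[str, list[str]] = {}
    for t, grp in df.groupby(df.columns[0], sort=False):
        out[str(t)] = list(grp.iloc[:, 1])
    return out


def write_marker_lists(markers: dict[str, list[str]], path: str) -> None:
    rows = [{"cell_type": t, "feature": f} for t, feats in markers.items() for f in feats]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
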