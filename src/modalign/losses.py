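"""The five training objectives and their weighted combination.

The total objective is

    L = L_CE + 0.1 * L_PR + alpha * L_CL + beta * L_FA + gamma * L_SC

where

* **CE** — cross-entropy of the classifier on the labeled reference batch;
* **PR** — projection regularization: the reciprocal of the query batch's
  total absolute deviation about the per-dimension embedding means, plus the
  mean absolute off-diagonal Pearson correlation and mean absolute
  per-dimension mean of both batches' embeddings (keeps the embedding
  spread-out, decorrelated, and centered);
* **CL** — a temperature-scaled contrastive loss that keeps each query
  cell close (in cosine similarity) to a neighbor from the kNN graph of
  the raw query data, against the other batch members as negatives;
* **FA** — feature alignment: the negated mean best-match cosine
  similarity between the top fraction of query cells and their most
  similar reference cells, pulling likely cross-domain pairs together;
* **SC** — sparse center loss: attention-weighted squared distance of each
  embedding to its (dynamically updated) class center, using true labels
  on the reference and pseudo-labels on the query.

All loss functions accept :class:`~modalign._autodiff.Tensor`,
:class:`~modalign.networks.EmbeddingBatch`, or plain arrays, and return a
``Tensor`` so gradients can flow; use ``.item()`` for the scalar value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

EPS = 1e-8


def _t(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if hasattr(x, "d"):  # EmbeddingBatch
        return Tensor(np.asarray(x.d))
    return Tensor(np.asarray(x, dtype=np.float64))


@dataclass
class ClassCenters:
    """K x m dynamic per-type embedding centroids."""

    c: np.ndarray
    update_rate: float = 0.5

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.float64)
        if not (0 < self.update_rate <= 1):
            raise ValueError("update_rate must be in (0, 1]")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("non-finite centers")

    @classmethod
    def zeros(cls, K: int, m: int, update_rate: float = 0.5) -> "ClassCenters":
        return cls(c=np.zeros((K, m)), update_rate=update_rate)


@dataclass
class LossBreakdown:
    l_ce: float
    l_pr: float
    l_cl: float
    l_fa: float
    l_sc: float
    total: float


# ----------------------------------------------------------------------

def ce_loss(p, y) -> Tensor:
    """Mean negative log-probability of the true class over the batch."""
    p = _t(p.p) if hasattr(p, "p") else _t(p)
    y = np.asarray(y, dtype=np.int64)
    if y.size == 0:
        raise ValueError("empty batch")
    K = p.shape[1]
    if np.any((y < 0) | (y >= K)):
        raise ValueError("label out of range")
    picked = p[(np.arange(y.size), y)]
    return -((picked + 1e-12).log().mean())


def pr_loss(d_q, d_r, eps: float = EPS) -> Tensor:
    """Projection regularization over the two embedding batches.

    The deviation (spread) term covers the query batch only; the
    correlation and mean terms cover both batches.
    """
    d_q, d_r = _t(d_q), _t(d_r)
    if d_q.shape[0] < 2 or d_r.shape[0] < 2:
        raise ValueError("pr_loss needs at least two cells per batch")
    q_mean = d_q.mean(axis=0, keepdims=True)
    r_mean = d_r.mean(axis=0, keepdims=True)
    m = d_q.shape[1]
    # reciprocal of mean-over-cells, summed-over-dimensions absolute deviation
    dev = (d_q - q_mean).abs().sum(axis=1).mean()
    term_dev = 1.0 / (dev + eps)
    term_corr_q = _mean_abs_offdiag_corr(d_q, eps)
    term_corr_r = _mean_abs_offdiag_corr(d_r, eps)
    term_mean_q = q_mean.abs().sum() / m
    term_mean_r = r_mean.abs().sum() / m
    return term_dev + term_corr_q + term_corr_r + term_mean_q + term_mean_r


def _mean_abs_offdiag_corr(d: Tensor, eps: float) -> Tensor:
    """(1/m^2) sum_{i != j} |Pearson corr of embedding dims i, j|."""
    n, m = d.shape
    centered = d - d.mean(axis=0, keepdims=True)
    cov = (centered.T @ centered) / n
    # tiny shift keeps the sqrt differentiable at zero-variance dimensions
    std = (cov[(np.arange(m), np.arange(m))] + 1e-24) ** 0.5
    denom = std.reshape(m, 1) * std.reshape(1, m) + eps  # zero-variance dims -> corr 0
    corr = cov / denom
    mask = 1.0 - np.eye(m)
    return (corr.abs() * mask).sum() / (m * m)


def _row_normalize(d: Tensor, eps: float = EPS) -> Tensor:
    norms = ((d**2).sum(axis=1, keepdims=True) + 1e-24) ** 0.5
    return d / (norms + eps)


def cl_loss(d_q, d_pos, tau: float) -> Tensor:
    """Neighborhood-preserving contrastive loss over a query batch.

    ``d_pos`` holds, row-aligned with ``d_q``, the embedding of one sampled
    kNN-graph neighbor per anchor (the positive).  The other members of the
    query batch serve as negatives.  Similarity is cosine, scaled by the
    temperature ``tau``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    d_q, d_pos = _t(d_q), _t(d_pos)
    n = d_q.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    qn = _row_normalize(d_q)
    pn = _row_normalize(d_pos)
    s_pos = (qn * pn).sum(axis=1) / tau                    # (n,)
    s_neg = (qn @ qn.T) / tau                              # (n, n)
    # stable softmax: shift by the row max over {positive} U {negatives}
    neg_mask = 1.0 - np.eye(n)
    shift = np.maximum(s_pos.data, np.where(neg_mask, s_neg.data, -np.inf).max(axis=1))
    exp_pos = (s_pos - Tensor(shift)).exp()
    exp_neg = ((s_neg - Tensor(shift[:, None])).exp() * neg_mask).sum(axis=1)
    return -((exp_pos / (exp_pos + exp_neg)).log().mean())


def fa_loss(d_q, d_r, p_frac: float = 0.2) -> Tensor:
    """Negated mean best-match cosine similarity over the top query cells.

    For each query cell the best cosine similarity over all reference cells
    is taken; the top ``p_frac`` fraction of query cells by that value form
    the aligned set, and the loss is minus the mean of their best matches.
    Ties at the selection boundary break by ascending cell index.
    """
    if not (0 < p_frac <= 1):
        raise ValueError("p_frac must be in (0, 1]")
    d_q, d_r = _t(d_q), _t(d_r)
    if d_q.shape[0] == 0 or d_r.shape[0] == 0:
        raise ValueError("empty batch")
    qn = _row_normalize(d_q)
    rn = _row_normalize(d_r)
    sims = qn @ rn.T                                        # (nq, nr)
    best_idx = sims.data.argmax(axis=1)                     # fixed for the subgradient
    best = sims[(np.arange(sims.shape[0]), best_idx)]       # (nq,)
    nq = best.shape[0]
    n_sel = max(1, int(np.floor(p_frac * nq + 1e-9)))
    order = np.lexsort((np.arange(nq), -best.data))[:n_sel]
    return -(best[order].mean())


def sc_loss(d, labels, a, centers: ClassCenters) -> Tensor:
    """Attention-weighted squared distance to class centers, averaged.

    Centers are treated as constants; they are maintained separately by
    :func:`update_centers`.
    """
    d = _t(d)
    a = _t(a.a if hasattr(a, "a") else a)
    labels = np.asarray(labels, dtype=np.int64)
    if a.shape != d.shape:
        raise ValueError("attention weights must match embedding shape")
    K = centers.c.shape[0]
    if np.any((labels < 0) | (labels >= K)):
        raise ValueError("label out of range")
    target = Tensor(centers.c[labels].astype(d.dtype))
    return (a * (d - target) ** 2).sum() / d.shape[0]


def update_centers(centers: ClassCenters, d, labels) -> ClassCenters:
    """Move each class center part-way toward its batch mean.

    ``c_k <- c_k - update_rate * (c_k - mean of class-k embeddings)``;
    classes absent from the batch keep their centers.
    """
    d = np.asarray(d.d if hasattr(d, "d") else (d.data if isinstance(d, Tensor) else d), dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    c = centers.c.copy()
    for k in np.unique(labels):
        batch_mean = d[labels == k].mean(axis=0)
        c[k] = c[k] - centers.update_rate * (c[k] - batch_mean)
    return ClassCenters(c=c, update_rate=centers.update_rate)


def total_loss(l_ce, l_pr, l_cl, l_fa, l_sc, alpha: float, beta: float, gamma: float):
    """Combine the five terms with the fixed 0.1 PR coefficient.

    Returns ``(breakdown, total)`` where ``total`` is a Tensor when any
    input is one (so gradients can flow) and the breakdown holds floats.
    """
    for w in (alpha, beta, gamma):
        if not np.isfinite(w) or w < 0:
            raise ValueError("loss weights must be finite and nonnegative")

    def val(x):
        return float(x.item()) if isinstance(x, Tensor) else float(x)

    total = l_ce + 0.1 * l_pr + alpha * l_cl + beta * l_fa + gamma * l_sc
    breakdown = LossBreakdown(
        l_ce=val(l_ce), l_pr=val(l_pr), l_cl=val(l_cl), l_fa=val(l_fa), l_sc=val(l_sc),
        total=val(total),
    )
    return breakdown, total
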