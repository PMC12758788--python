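"""Semi-supervised training: paired mini-batches, pseudo-labels, centers,
scenario presets, and early stopping.

Each step draws equal-size mini-batches ``B_r`` (labeled reference) and
``B_q`` (unlabeled query), embeds both plus one sampled kNN-graph neighbor
per query cell, evaluates the five losses, and takes one SGD-with-momentum
step.  Query cells carry pseudo-labels — the classifier's current
prediction, refreshed for the cells of each batch — which join the sparse
center loss and the center updates after a warm-up period.  Training halts
at the scenario's iteration cap, or earlier once the sparse center loss
has been flat (|change| < ``sc_tolerance``) for ``patience`` consecutive
iterations (plateau rule disabled when gamma = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from .io_prep import ExpressionMatrix, NeighborGraph, build_knn_graph, intersect_features, log_normalize
from .losses import (
    ClassCenters,
    LossBreakdown,
    ce_loss,
    cl_loss,
    fa_loss,
    pr_loss,
    sc_loss,
    total_loss,
    update_centers,
)
from .networks import Model, ModelConfig, init_model

PRESET_NAMES = ("matched_rna_atac", "unmatched_rna_atac", "rna_to_rna", "atac_to_atac")


@dataclass
class ScenarioConfig:
    """Hyperparameters of one training run.

    The four named presets carry the published weight sets; ``custom``
    starts from the cross-modality defaults and is meant to be edited.
    """

    scenario: str = "custom"
    alpha: float = 0.06
    beta: float = 0.05
    gamma: float = 0.01
    tau: float = 0.04
    p_frac: float = 0.2
    batch_size: int = 512
    learning_rate: float = 0.001
    momentum: float = 0.9
    max_iterations: int = 3000
    patience: int = 20
    sc_tolerance: float = 1e-4
    confidence_threshold: float = 0.95
    warmup_iterations: int = 100
    center_update_rate: float = 0.5
    knn_k: int = 15
    pca_components: int = 50
    hidden_dims: list[int] = field(default_factory=lambda: [1024])
    m: int = 64
    e_dim: int = 32
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.confidence_threshold < 1):
            raise ValueError("confidence_threshold must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


_PRESETS: dict[str, dict] = {
    # cross-modality scenarios: cap 3000
    "matched_rna_atac": dict(alpha=0.06, beta=0.05, gamma=0.01, tau=0.04, max_iterations=3000),
    "unmatched_rna_atac": dict(alpha=1.2, beta=0.05, gamma=0.01, tau=0.8, max_iterations=3000),
    # same-modality label propagation: cap 200
    "rna_to_rna": dict(alpha=0.1, beta=0.0, gamma=0.1, tau=0.8, max_iterations=200),
    "atac_to_atac": dict(alpha=0.1, beta=0.0, gamma=0.001, tau=0.8, max_iterations=200),
}


def scenario_preset(scenario: str, **overrides) -> ScenarioConfig:
    """The published hyperparameter set for a named scenario."""
    if scenario not in _PRESETS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {PRESET_NAMES}")
    kwargs = dict(_PRESETS[scenario])
    kwargs.update(overrides)
    return ScenarioConfig(scenario=scenario, **kwargs)


@dataclass
class TrainState:
    iteration: int
    centers: ClassCenters
    pseudo_labels: np.ndarray       # (n_query,) int
    pseudo_confidence: np.ndarray   # (n_query,)
    sc_loss_history: list[float]
    rng: np.random.Generator


class _StreamSampler:
    """Without-replacement index stream that reshuffles when exhausted."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self._perm = rng.permutation(n)
        self._pos = 0

    def draw(self, size: int) -> np.ndarray:
        out = []
        need = size
        while need > 0:
            take = min(need, self.n - self._pos)
            out.append(self._perm[self._pos : self._pos + take])
            self._pos += take
            need -= take
            if self._pos == self.n:
                self._perm = self.rng.permutation(self.n)
                self._pos = 0
        return np.concatenate(out)


def sample_minibatches(sampler_r: _StreamSampler, sampler_q: _StreamSampler, batch_size: int):
    """Equal-size index batches from the two streams."""
    return sampler_r.draw(batch_size), sampler_q.draw(batch_size)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data = p.data + v


def assign_pseudo_labels(model: Model, query_x: np.ndarray, state: TrainState, indices=None) -> TrainState:
    """Set pseudo-labels to the classifier's current predictions.

    With ``indices`` given, only those query cells are re-scored (the
    per-batch refinement used during training); otherwise all cells are.
    """
    if indices is None:
        indices = np.arange(query_x.shape[0])
    x = np.asarray(query_x[indices], dtype=np.dtype(model.config.dtype))
    d = model.forward_embed(Tensor(x), training=False)
    p = model.forward_probs(d).data
    state.pseudo_labels[indices] = p.argmax(axis=1)
    state.pseudo_confidence[indices] = p.max(axis=1)
    return state


def train_step(
    model: Model,
    optimizer: SGD,
    ref_x: np.ndarray,
    ref_y: np.ndarray,
    query_x: np.ndarray,
    graph: NeighborGraph,
    config: ScenarioConfig,
    state: TrainState,
    batch_r: np.ndarray,
    batch_q: np.ndarray,
) -> LossBreakdown:
    """One optimization step over paired mini-batches."""
    dtype = np.dtype(model.config.dtype)
    nb = graph.neighbor_indices[batch_q]
    pos_idx = nb[np.arange(len(batch_q)), state.rng.integers(0, nb.shape[1], size=len(batch_q))]

    x_cat = np.concatenate([ref_x[batch_r], query_x[batch_q], query_x[pos_idx]]).astype(dtype)
    model.zero_grad()
    d_cat = model.forward_embed(Tensor(x_cat), training=True)
    n_r, n_q = len(batch_r), len(batch_q)
    d_r = d_cat[np.arange(n_r)]
    d_q = d_cat[np.arange(n_r, n_r + n_q)]
    d_pos = d_cat[np.arange(n_r + n_q, n_r + n_q + len(pos_idx))]

    probs_r = model.forward_probs(d_r)
    l_ce = ce_loss(probs_r, ref_y[batch_r])
    l_pr = pr_loss(d_q, d_r)
    l_cl = cl_loss(d_q, d_pos, config.tau)
    l_fa = fa_loss(d_q, d_r, config.p_frac)

    # refresh pseudo-labels of this batch's query cells from current outputs
    probs_q = model.forward_probs(d_q).data
    state.pseudo_labels[batch_q] = probs_q.argmax(axis=1)
    state.pseudo_confidence[batch_q] = probs_q.max(axis=1)

    use_query_sc = state.iteration >= config.warmup_iterations
    if use_query_sc:
        d_sc = concat([d_r, d_q], axis=0)
        labels_sc = np.concatenate([ref_y[batch_r], state.pseudo_labels[batch_q]])
    else:
        d_sc = d_r
        labels_sc = ref_y[batch_r]
    a_sc, _, _, _ = model.forward_attention(d_sc, training=True)
    l_sc = sc_loss(d_sc, labels_sc, a_sc, state.centers)

    breakdown, total = total_loss(l_ce, l_pr, l_cl, l_fa, l_sc, config.alpha, config.beta, config.gamma)
    if not np.isfinite(breakdown.total):
        bad = [n for n, v in asdict(breakdown).items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite loss terms at iteration {state.iteration}: {bad}")
    total.backward()
    optimizer.step()

    state.centers = update_centers(state.centers, d_sc.data, labels_sc)
    state.iteration += 1
    state.sc_loss_history.append(breakdown.l_sc)
    if len(state.sc_loss_history) > config.patience + 1:
        del state.sc_loss_history[: -config.patience - 1]
    return breakdown


def prepare(ref_raw: ExpressionMatrix, query_raw: ExpressionMatrix, config: ScenarioConfig):
    """Intersect features, build the raw-query kNN graph, log-normalize."""
    ref_i, query_i = intersect_features(ref_raw, query_raw)
    graph = build_knn_graph(query_i, n_components=config.pca_components, k=config.knn_k)
    return log_normalize(ref_i), log_normalize(query_i), graph


def fit(
    ref: ExpressionMatrix,
    query: ExpressionMatrix,
    config: ScenarioConfig,
    graph: NeighborGraph | None = None,
) -> tuple[Model, TrainState, pd.DataFrame]:
    """Train on an intersected, log-normalized reference/query pair.

    If ``graph`` is omitted it is built from ``query`` as given; to follow
    the intended protocol (graph from the *raw* query) use :func:`prepare`
    or pass a precomputed graph.

    Returns ``(model, state, log)`` with one log row per iteration.
    """
    if ref.labels is None:
        raise ValueError("reference must carry labels")
    if ref.feature_names != query.feature_names:
        raise ValueError("feature spaces differ; run intersect_features first")
    if graph is None:
        graph = build_knn_graph(query, n_components=config.pca_components, k=config.knn_k)

    class_names = sorted(set(ref.labels))
    class_index = {c: i for i, c in enumerate(class_names)}
    ref_y = np.array([class_index[l] for l in ref.labels], dtype=np.int64)

    model_config = ModelConfig(
        input_dim=ref.n_features,
        K=len(class_names),
        hidden_dims=list(config.hidden_dims),
        m=config.m,
        e_dim=config.e_dim,
        dtype=config.dtype,
    )
    model = init_model(model_config, seed=config.seed)
    model.feature_names = list(ref.feature_names)
    model.class_names = class_names

    rng = np.random.default_rng(config.seed)
    state = TrainState(
        iteration=0,
        centers=ClassCenters.zeros(model_config.K, config.m, update_rate=config.center_update_rate),
        pseudo_labels=np.zeros(query.n_cells, dtype=np.int64),
        pseudo_confidence=np.zeros(query.n_cells),
        sc_loss_history=[],
        rng=rng,
    )
    state = assign_pseudo_labels(model, query.values, state)

    optimizer = SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    sampler_r = _StreamSampler(ref.n_cells, rng)
    sampler_q = _StreamSampler(query.n_cells, rng)

    rows = []
    flat_run = 0
    while state.iteration < config.max_iterations:
        batch_r, batch_q = sample_minibatches(sampler_r, sampler_q, config.batch_size)
        breakdown = train_step(
            model, optimizer, ref.values, ref_y, query.values, graph, config, state, batch_r, batch_q
        )
        rows.append({"iteration": state.iteration, **asdict(breakdown)})
        # sparse-loss plateau rule (only meaningful when the SC term is live)
        if config.gamma > 0 and len(state.sc_loss_history) >= 2:
            if abs(state.sc_loss_history[-1] - state.sc_loss_history[-2]) < config.sc_tolerance:
                flat_run += 1
            else:
                flat_run = 0
            if flat_run >= config.patience:
                break
    log = pd.DataFrame(rows)
    return model, state, log
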