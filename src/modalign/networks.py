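"""The feature extractor ``f``, classifier ``c``, and attention network ``A``.

``f`` projects cells from both domains into a shared m-dimensional
embedding space (default m = 64) through fully connected hidden layers with
batch normalization and ReLU.  ``c`` is a linear layer from the embedding
to K class logits, softmaxed into per-type probabilities.  The attention
network produces, for every embedding dimension j, an inclusion score
``p_in`` and an exclusion score ``p_ex`` from a shared latent (the CE-Unit:
linear m -> e_dim, batch norm, tanh); the attention weight is the two-way
softmax ``a = exp(p_in) / (exp(p_in) + exp(p_ex))``, i.e. the logistic
function of ``p_in - p_ex``, so every weight lies strictly in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor


@dataclass
class ModelConfig:
    input_dim: int
    K: int
    hidden_dims: list[int] = field(default_factory=lambda: [1024])
    m: int = 64
    e_dim: int = 32
    dtype: str = "float32"

    def __post_init__(self):
        if self.m <= 0 or self.e_dim <= 0:
            raise ValueError("m and e_dim must be positive")
        if self.K < 2:
            raise ValueError("need at least two reference cell types")
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")


@dataclass
class EmbeddingBatch:
    """Per-cell embeddings d (n x m)."""

    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d)
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite embedding values")


@dataclass
class ClassProbabilities:
    """Softmax class probabilities with argmax prediction per cell."""

    p: np.ndarray
    predicted_class: np.ndarray
    confidence: np.ndarray

    @classmethod
    def from_probs(cls, p: np.ndarray) -> "ClassProbabilities":
        p = np.asarray(p)
        return cls(p=p, predicted_class=p.argmax(axis=1), confidence=p.max(axis=1) if p.size else np.zeros(p.shape[0]))


@dataclass
class AttentionWeights:
    """Per-dimension inclusion/exclusion attention for each cell."""

    a: np.ndarray        # (n, m), strictly in (0, 1)
    latent: np.ndarray   # (n, e_dim) CE-Unit outputs
    scores: tuple[np.ndarray, np.ndarray]  # (p_in, p_ex), each (n, m)


# ----------------------------------------------------------------------
# Layers
# ----------------------------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype, gain: float = 2.0):
        scale = np.sqrt(gain / n_in)
        self.W = Tensor((rng.standard_normal((n_in, n_out)) * scale).astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, n: int, dtype, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool, update_stats: bool = True) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            if update_stats:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


# ----------------------------------------------------------------------
# Model
# ----------------------------------------------------------------------

class Model:
    """f + c + A with shared parameter bookkeeping.

    Construct via :func:`init_model`.  ``feature_names`` and ``class_names``
    are attached by training so checkpoints are self-describing.
    """

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = seed
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        # feature extractor f
        self.f_layers: list[tuple[Linear, BatchNorm1d]] = []
        n_in = config.input_dim
        for h in config.hidden_dims:
            self.f_layers.append((Linear(n_in, h, rng, dtype), BatchNorm1d(h, dtype)))
            n_in = h
        self.f_out = Linear(n_in, config.m, rng, dtype, gain=1.0)
        # classifier c
        self.c_head = Linear(config.m, config.K, rng, dtype, gain=1.0)
        # attention network A: CE-Unit + m two-logit heads
        self.ce_linear = Linear(config.m, config.e_dim, rng, dtype, gain=1.0)
        self.ce_bn = BatchNorm1d(config.e_dim, dtype)
        self.head_in = Linear(config.e_dim, config.m, rng, dtype, gain=1.0)
        self.head_ex = Linear(config.e_dim, config.m, rng, dtype, gain=1.0)

    # -- parameter plumbing -------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for lin, bn in self.f_layers:
            params += lin.parameters() + bn.parameters()
        for mod in (self.f_out, self.c_head, self.ce_linear, self.ce_bn, self.head_in, self.head_ex):
            params += mod.parameters()
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- differentiable forward passes --------------------------------
    def forward_embed(self, x: Tensor, training: bool = False, update_stats: bool = True) -> Tensor:
        h = x
        for lin, bn in self.f_layers:
            h = bn(lin(h), training, update_stats).relu()
        return self.f_out(h)

    def forward_logits(self, d: Tensor) -> Tensor:
        return self.c_head(d)

    def forward_probs(self, d: Tensor) -> Tensor:
        logits = self.forward_logits(d)
        shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=1, keepdims=True)

    def forward_attention(self, d: Tensor, training: bool = False, update_stats: bool = True):
        """Returns (a, latent, p_in, p_ex) as tensors."""
        latent = self.ce_bn(self.ce_linear(d), training, update_stats).tanh()
        p_in = self.head_in(latent)
        p_ex = self.head_ex(latent)
        a = (p_in - p_ex).sigmoid()  # == exp(p_in) / (exp(p_in) + exp(p_ex))
        return a, latent, p_in, p_ex


def init_model(config: ModelConfig, seed: int) -> Model:
    """Deterministically initialize a model from a seed."""
    return Model(config, seed)


# ----------------------------------------------------------------------
# Numpy-facing operations (evaluation mode)
# ----------------------------------------------------------------------

def embed(model: Model, x: np.ndarray) -> EmbeddingBatch:
    """Embed feature rows in evaluation mode (running batch-norm stats)."""
    x = np.asarray(x, dtype=np.dtype(model.config.dtype))
    if x.ndim != 2 or x.shape[1] != model.config.input_dim:
        raise ValueError(f"expected (n, {model.config.input_dim}) input, got {x.shape}")
    return EmbeddingBatch(d=model.forward_embed(Tensor(x), training=False).data)


def classify(model: Model, d: EmbeddingBatch) -> ClassProbabilities:
    if d.d.ndim != 2 or d.d.shape[1] != model.config.m:
        raise ValueError(f"expected (n, {model.config.m}) embeddings")
    p = model.forward_probs(Tensor(np.asarray(d.d, dtype=np.dtype(model.config.dtype)))).data
    return ClassProbabilities.from_probs(p)


def attention_weights(model: Model, d: EmbeddingBatch) -> AttentionWeights:
    if d.d.ndim != 2 or d.d.shape[1] != model.config.m:
        raise ValueError(f"expected (n, {model.config.m}) embeddings")
    a, latent, p_in, p_ex = model.forward_attention(Tensor(np.asarray(d.d, dtype=np.dtype(model.config.dtype))))
    return AttentionWeights(a=a.data, latent=latent.data, scores=(p_in.data, p_ex.data))


# ----------------------------------------------------------------------
# Checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(model: Model, path: str, feature_names=None, class_names=None) -> None:
    """Serialize parameters, running stats, and config to one .npz file."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    stats = {}
    for i, (_, bn) in enumerate(model.f_layers):
        stats[f"f_bn{i}_mean"], stats[f"f_bn{i}_var"] = bn.running_mean, bn.running_var
    stats["ce_bn_mean"], stats["ce_bn_var"] = model.ce_bn.running_mean, model.ce_bn.running_var
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "feature_names": list(feature_names) if feature_names is not None else getattr(model, "feature_names", None),
        "class_names": list(class_names) if class_names is not None else getattr(model, "class_names", None),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays, **stats)


def load_checkpoint(path: str) -> Model:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        model = Model(config, meta["seed"])
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i}"]
        for i, (_, bn) in enumerate(model.f_layers):
            bn.running_mean = data[f"f_bn{i}_mean"]
            bn.running_var = data[f"f_bn{i}_var"]
        model.ce_bn.running_mean = data["ce_bn_mean"]
        model.ce_bn.running_var = data["ce_bn_var"]
    if meta["feature_names"] is not None:
        model.feature_names = meta["feature_names"]
    if meta["class_names"] is not None:
        model.class_names = meta["class_names"]
    return model
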