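"""Synthetic paired reference/query domains with shared cell-type structure.

The generator emulates the situation a cross-modality annotator faces: two
cell-by-feature matrices whose cells come from the same underlying cell
types, but whose measurements live in different coordinate systems because
of modality and protocol effects.  Cells of type ``t`` are drawn around a
latent log-mean ``mu_t``; query cells see ``mu_t`` pushed through a fixed
random affine map whose deviation from the identity scales with
``shift_strength``.  Latent values are exponentiated to nonnegative
log-normal pseudo-counts, and multiplicative Bernoulli dropout thins them.
Optional novel types appear only in the query, for open-set evaluation.

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec; the same spec always produces bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_prep import ExpressionMatrix

#: Per-feature Gaussian noise s.d. around the latent type mean (log scale).
NOISE_SD = 1.0


@dataclass
class SyntheticSpec:
    """Parameters of a paired-domain simulation."""

    n_ref: int = 2000
    n_query: int = 2000
    n_features: int = 200
    K: int = 5
    n_novel: int = 0
    separation: float = 0.6
    shift_strength: float = 1.5
    dropout_rate: float = 0.2
    ref_proportions: list[float] | None = None     # length K
    query_proportions: list[float] | None = None   # length K + n_novel
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ref", "n_query", "n_features", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_novel < 0:
            raise ValueError("n_novel must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.shift_strength < 0:
            raise ValueError("shift_strength must be nonnegative")
        if self.ref_proportions is None:
            self.ref_proportions = [1.0 / self.K] * self.K
        if self.query_proportions is None:
            m = self.K + self.n_novel
            self.query_proportions = [1.0 / m] * m
        for props, n in ((self.ref_proportions, self.K), (self.query_proportions, self.K + self.n_novel)):
            if len(props) != n:
                raise ValueError(f"expected {n} proportions, got {len(props)}")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")
            if any(p < 0 for p in props):
                raise ValueError("proportions must be nonnegative")

    @property
    def type_names(self) -> list[str]:
        return [f"type_{t}" for t in range(self.K)]

    @property
    def novel_names(self) -> list[str]:
        return [f"novel_{t}" for t in range(self.n_novel)]


def _apportion(n: int, proportions: list[float]) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n cells to types."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    # hand leftover cells to the largest remainders; ties by type index
    order = np.lexsort((np.arange(len(raw)), -remainder))
    counts[order[:short]] += 1
    return counts


def _latent_structure(spec: SyntheticSpec, rng: np.random.Generator):
    """Draw the planted means and the cross-domain affine map."""
    F = spec.n_features
    base = rng.normal(0.0, 1.0, size=F)
    effects = rng.normal(0.0, 1.0, size=(spec.K + spec.n_novel, F))
    means = base + spec.separation * effects  # (K + n_novel, F)
    A = np.eye(F) + spec.shift_strength * rng.normal(0.0, 1.0, size=(F, F)) / np.sqrt(F)
    b = spec.shift_strength * rng.normal(0.0, 1.0, size=F)
    return means, A, b


def generate_paired_domains(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate the labeled reference and the query with held-out true labels.

    Returns ``(ref, query)``.  ``query.labels`` carries the ground-truth cell
    types (including novel ones); they exist for evaluation only and must
    not be shown to training.
    """
    rng = np.random.default_rng(spec.seed)
    means, A, b = _latent_structure(spec, rng)
    names = spec.type_names + spec.novel_names

    ref_counts = _apportion(spec.n_ref, spec.ref_proportions)
    q_counts = _apportion(spec.n_query, spec.query_proportions)

    def _domain(counts, mean_rows, prefix, shifted):
        blocks, labels = [], []
        for t, c in enumerate(counts):
            if c == 0:
                continue
            mu = mean_rows[t]
            if shifted:
                mu = A @ mu + b
            latent = mu + rng.normal(0.0, NOISE_SD, size=(c, spec.n_features))
            blocks.append(np.exp(latent))
            labels.extend([names[t]] * c)
        values = np.vstack(blocks)
        if spec.dropout_rate > 0:
            keep = rng.random(values.shape) >= spec.dropout_rate
            values = values * keep
        ids = [f"{prefix}_{i}" for i in range(values.shape[0])]
        return values, ids, labels

    ref_vals, ref_ids, ref_labels = _domain(ref_counts, means[: spec.K], "ref", shifted=False)
    q_vals, q_ids, q_labels = _domain(q_counts, means, "query", shifted=True)

    ref = ExpressionMatrix(values=ref_vals, cell_ids=ref_ids, feature_names=_feature_names(spec), labels=ref_labels)
    query = ExpressionMatrix(values=q_vals, cell_ids=q_ids, feature_names=_feature_names(spec), labels=q_labels)
    return ref, query


def _feature_names(spec: SyntheticSpec) -> list[str]:
    return [f"feat_{j}" for j in range(spec.n_features)]


def generate_marker_lists(spec: SyntheticSpec, n_markers: int = 20) -> dict[str, list[str]]:
    """Planted ground-truth marker features for each shared type.

    For type ``t`` the markers are the ``n_markers`` features with the
    largest ``|mu_t - mean over the other shared types|`` in the planted
    latent means — the features the generator itself made discriminative.
    Ties break by ascending feature index.
    """
    if n_markers > spec.n_features:
        raise ValueError("n_markers exceeds n_features")
    rng = np.random.default_rng(spec.seed)
    means, _, _ = _latent_structure(spec, rng)
    shared = means[: spec.K]
    feature_names = _feature_names(spec)
    out: dict[str, list[str]] = {}
    for t in range(spec.K):
        others = np.delete(shared, t, axis=0).mean(axis=0)
        gap = np.abs(shared[t] - others)
        order = np.lexsort((np.arange(spec.n_features), -gap))
        out[spec.type_names[t]] = [feature_names[j] for j in order[:n_markers]]
    return out
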