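import numpy as np
import pytest

from modalign import ExpressionMatrix, ModelConfig, init_model
from modalign.io_prep import log_normalize
from modalign.synthetic import SyntheticSpec, generate_paired_domains


def make_matrix(values, labels=None, prefix="c"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        feature_names=[f"g{j}" for j in range(values.shape[1])],
        labels=labels,
    )


def nearest_centroid_accuracy(ref, query):
    """Reference-only nearest-centroid classifier scored on the query."""
    rn = log_normalize(ref).values
    qn = log_normalize(query).values
    types = sorted(set(ref.labels))
    cents = np.stack([rn[np.array(ref.labels) == t].mean(axis=0) for t in types])
    d2 = ((qn[:, None, :] - cents[None]) ** 2).sum(axis=-1)
    pred = [types[i] for i in d2.argmin(axis=1)]
    return float(np.mean([p == t for p, t in zip(pred, query.labels)]))


@pytest.fixture(scope="session")
def small_pair():
    """A small but nontrivial paired-domain dataset (shared structure, mild shift)."""
    spec = SyntheticSpec(n_ref=150, n_query=150, n_features=40, K=3, separation=1.5,
                         shift_strength=0.3, dropout_rate=0.1, seed=7)
    return generate_paired_domains(spec)


@pytest.fixture
def tiny_model():
    return init_model(ModelConfig(input_dim=6, K=3, hidden_dims=[5], m=4, e_dim=3, dtype="float64"), seed=0)
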