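"""Fixed-parameter annotation of query cells with "Unknown" rejection.

At prediction time the feature extractor and classifier run in evaluation
mode with frozen parameters.  A cell is assigned the argmax cell type only
when its maximum class probability strictly exceeds the confidence
threshold (default 0.95); otherwise it is labeled ``"Unknown"``, which is
how query-only novel types are surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_prep import ExpressionMatrix
from .networks import Model, classify, embed

UNKNOWN = "Unknown"


@dataclass
class PredictionResult:
    cell_ids: list[str]
    assigned_type: list[str]
    confidence: np.ndarray
    full_probabilities: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        if not np.allclose(self.confidence, self.full_probabilities.max(axis=1)):
            raise ValueError("confidence must equal the row maximum probability")


def predict(model: Model, query: ExpressionMatrix, threshold: float = 0.95) -> PredictionResult:
    """Annotate query cells, rejecting low-confidence cells as Unknown."""
    class_names = getattr(model, "class_names", None)
    if class_names is None:
        class_names = [f"class_{k}" for k in range(model.config.K)]
    feature_names = getattr(model, "feature_names", None)
    if feature_names is not None and list(query.feature_names) != list(feature_names):
        raise ValueError("query features do not match the features the model was trained on")
    probs = classify(model, embed(model, query.values))
    assigned = [
        class_names[k] if conf > threshold else UNKNOWN
        for k, conf in zip(probs.predicted_class, probs.confidence)
    ]
    return PredictionResult(
        cell_ids=list(query.cell_ids),
        assigned_type=assigned,
        confidence=probs.confidence,
        full_probabilities=probs.p,
        class_names=list(class_names),
    )


def export_predictions(result: PredictionResult, path: str, include_probabilities: bool = True) -> None:
    """Write predictions as TSV: cell_id, assigned_type, confidence[, p_<class>...]."""
    data = {
        "cell_id": result.cell_ids,
        "assigned_type": result.assigned_type,
        "confidence": result.confidence,
    }
    if include_probabilities:
        for k, name in enumerate(result.class_names):
            data[f"p_{name}"] = result.full_probabilities[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_predictions(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "assigned_type": str})
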