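"""Closed- and open-set evaluation of transferred labels.

Closed-set: accuracy and macro-F1 against the held-out query labels.
Open-set: query cells whose true type is absent from the reference are
"novel"; they count as correct only when predicted ``"Unknown"``.  Novelty
detection is scored by AUROC with ``1 - confidence`` as the novelty score,
and by OSCR — the area under the curve of correct-classification rate on
known-type cells versus false-positive rate on novel cells as the
confidence threshold sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score as _sk_auroc

from .predict import UNKNOWN


def _openset_truth(true_labels, known_types):
    """Map novel true types to Unknown when a known-type set is given."""
    if known_types is None:
        return list(true_labels)
    known = set(known_types)
    return [t if t in known else UNKNOWN for t in true_labels]


def accuracy(true_labels, predicted_labels, known_types=None) -> float:
    """Fraction of exact matches; novel types count as correct iff the
    prediction is Unknown (open-set mode, triggered by ``known_types``)."""
    t = _openset_truth(true_labels, known_types)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    if not t:
        raise ValueError("empty input")
    return float(np.mean([a == b for a, b in zip(t, p)]))


def macro_f1(true_labels, predicted_labels, known_types=None) -> float:
    """Unweighted mean of per-class F1 over the classes present in truth.

    Classes that appear only in predictions (e.g. Unknown in closed-set
    mode) are excluded from the average.
    """
    t = _openset_truth(true_labels, known_types)
    p = list(predicted_labels)
    if not t:
        raise ValueError("empty input")
    classes = sorted(set(t))
    return float(_sk_f1(t, p, labels=classes, average="macro", zero_division=0))


def per_class_f1(true_labels, predicted_labels, known_types=None) -> dict[str, float]:
    t = _openset_truth(true_labels, known_types)
    classes = sorted(set(t))
    scores = _sk_f1(t, list(predicted_labels), labels=classes, average=None, zero_division=0)
    return dict(zip(classes, map(float, scores)))


def confusion(true_labels, predicted_labels, known_types=None) -> pd.DataFrame:
    t = _openset_truth(true_labels, known_types)
    p = list(predicted_labels)
    classes = sorted(set(t) | set(p))
    mat = _sk_confusion(t, p, labels=classes)
    return pd.DataFrame(mat, index=classes, columns=classes)


def novelty_auroc(is_novel, confidence) -> float:
    """AUROC for detecting novel cells with 1 - confidence as the score."""
    is_novel = np.asarray(is_novel, dtype=bool)
    confidence = np.asarray(confidence, dtype=float)
    if is_novel.all() or not is_novel.any():
        raise ValueError("need both novel and non-novel cells")
    return float(_sk_auroc(is_novel, 1.0 - confidence))


def oscr(true_labels, predicted_labels, confidence, novel_mask) -> float:
    """Open-set classification rate: area under CCR-vs-FPR.

    Sweeping the confidence threshold theta downward, CCR(theta) is the
    fraction of known-type cells that are correctly classified with
    confidence above theta, and FPR(theta) is the fraction of novel cells
    with confidence above theta.  The area is taken by the trapezoid rule
    over the full sweep.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    confidence = np.asarray(confidence, dtype=float)
    novel_mask = np.asarray(novel_mask, dtype=bool)
    n_novel = int(novel_mask.sum())
    n_known = int((~novel_mask).sum())
    if n_novel == 0 or n_known == 0:
        raise ValueError("need both novel and known cells")
    correct_known = np.array(
        [(not nov) and (p == t) for t, p, nov in zip(true_labels, predicted_labels, novel_mask)]
    )
    thresholds = np.unique(confidence)[::-1]
    ccr = [0.0]
    fpr = [0.0]
    for theta in thresholds:
        above = confidence >= theta
        ccr.append(float((correct_known & above).sum()) / n_known)
        fpr.append(float((novel_mask & above).sum()) / n_novel)
    ccr.append(float(correct_known.sum()) / n_known)
    fpr.append(1.0)
    return float(np.trapezoid(ccr, fpr))


@dataclass
class EvaluationReport:
    accuracy: float
    macro_f1: float
    per_class_f1: dict[str, float]
    confusion: pd.DataFrame
    auroc: float | None = None
    oscr: float | None = None

    def to_json(self) -> str:
        payload = {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": self.per_class_f1,
            "auroc": self.auroc,
            "oscr": self.oscr,
        }
        return json.dumps(payload, indent=2)

    def __str__(self) -> str:
        lines = [f"accuracy : {self.accuracy:.4f}", f"macro-F1 : {self.macro_f1:.4f}"]
        if self.auroc is not None:
            lines.append(f"AUROC    : {self.auroc:.4f}")
        if self.oscr is not None:
            lines.append(f"OSCR     : {self.oscr:.4f}")
        for cls, f1 in self.per_class_f1.items():
            lines.append(f"  F1[{cls}] = {f1:.4f}")
        return "\n".join(lines)


def evaluate_predictions(true_labels, predicted_labels, confidence=None, known_types=None,
                         argmax_labels=None) -> EvaluationReport:
    """Full report; open-set metrics appear when known_types and confidence
    are given and the truth actually contains novel types.

    OSCR sweeps the confidence threshold itself, so it should see the raw
    argmax classifications (``argmax_labels``), not already-thresholded
    assignments; when ``argmax_labels`` is omitted the given predictions
    are used and cells rejected as Unknown count as errors (conservative).
    """
    rep = EvaluationReport(
        accuracy=accuracy(true_labels, predicted_labels, known_types),
        macro_f1=macro_f1(true_labels, predicted_labels, known_types),
        per_class_f1=per_class_f1(true_labels, predicted_labels, known_types),
        confusion=confusion(true_labels, predicted_labels, known_types),
    )
    if known_types is not None and confidence is not None:
        novel = np.array([t not in set(known_types) for t in true_labels])
        if novel.any() and (~novel).any():
            rep.auroc = novelty_auroc(novel, confidence)
            labels_for_oscr = predicted_labels if argmax_labels is None else argmax_labels
            rep.oscr = oscr(true_labels, labels_for_oscr, confidence, novel)
    return rep
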