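"""Confusion-matrix construction and the reported performance measures.

Positive class is ASD (label 1).  Micro/macro averages use standard
one-vs-rest pooling over the two classes; for single-label binary
prediction this makes micro-averaged precision and recall both equal the
accuracy.  Undefined ratios (0/0) evaluate to 0 with a logged warning.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column order used for the one-row CSV/JSON export
SCORE_FIELDS = (
    "accuracy",
    "error",
    "precision",
    "recall",
    "micro_precision",
    "macro_precision",
    "micro_recall",
    "macro_recall",
    "f1",
)


@dataclasses.dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(truth, pred) -> ConfusionMatrix:
    """Cross-tabulate 0/1 label vectors (positive class = 1)."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    for name, v in (("truth", truth), ("pred", pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside the trained class set {{0, 1}}")
    return ConfusionMatrix(
        tp=int(((truth == 1) & (pred == 1)).sum()),
        fp=int(((truth == 0) & (pred == 1)).sum()),
        fn=int(((truth == 1) & (pred == 0)).sum()),
        tn=int(((truth == 0) & (pred == 0)).sum()),
    )


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", what)
        return 0.0
    return num / den


def scores(cm: ConfusionMatrix) -> dict[str, float]:
    """All confusion-derived measures, as fractions in [0, 1]."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    accuracy = _ratio(tp + tn, cm.n, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    # one-vs-rest view of the negative class
    precision_neg = _ratio(tn, tn + fn, "negative-class precision")
    recall_neg = _ratio(tn, tn + fp, "negative-class recall")
    # micro: pool per-class TP and (TP+FP) / (TP+FN) counts over both classes
    micro_precision = _ratio(tp + tn, tp + fp + tn + fn, "micro precision")
    micro_recall = _ratio(tp + tn, tp + fn + tn + fp, "micro recall")
    macro_precision = (precision + precision_neg) / 2.0
    macro_recall = (recall + recall_neg) / 2.0
    if macro_precision + macro_recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * macro_precision * macro_recall / (macro_precision + macro_recall)
    return {
        "accuracy": accuracy,
        "error": 1.0 - accuracy,
        "precision": precision,
        "recall": recall,
        "micro_precision": micro_precision,
        "macro_precision": macro_precision,
        "micro_recall": micro_recall,
        "macro_recall": macro_recall,
        "f1": f1,
    }


def scores_frame(s: dict[str, float]) -> pd.DataFrame:
    """One-row DataFrame in the canonical column order (for CSV export)."""
    return pd.DataFrame([{k: s[k] for k in SCORE_FIELDS}])
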