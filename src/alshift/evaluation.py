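"""Confusion-count metrics (accuracy, precision, recall, F1, AUC) and the
snapshot-by-test-set evaluation matrix.

The positive class is ``CLASS1`` ("ASD").  Zero-denominator precision/recall
return 0 with an explicit ``degenerate`` flag rather than raising, so sweeps
stay honest without crashing.  ``M``/``M_av`` semantics: the combined test
set is the plain concatenation T1+T2 and metrics are pooled over it, not
averaged per set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CLASS0, CLASS1, ImageSample, labels_of
from .errors import ConfigurationError

COMBINED_TAG = "T1+T2"


@dataclass(frozen=True)
class ConfusionCounts:
    Tp: int
    Tn: int
    Fp: int
    Fn: int

    def __post_init__(self) -> None:
        if min(self.Tp, self.Tn, self.Fp, self.Fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.Tp + self.Tn + self.Fp + self.Fn


@dataclass(frozen=True)
class MetricsRecord:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    n_samples: int
    weights_tag: str = ""
    test_set_tag: str = ""
    degenerate: tuple[str, ...] = ()
    macro_precision: float | None = None
    macro_recall: float | None = None
    macro_f1: float | None = None


def confusion_counts(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """Tally Tp/Tn/Fp/Fn with ``CLASS1`` as positive."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label sequences must be equal-length 1-D, got {t.shape} vs {p.shape}")
    valid = {CLASS0, CLASS1}
    if not set(np.unique(t)).issubset(valid) or not set(np.unique(p)).issubset(valid):
        raise ValueError("labels must be drawn from {class0, class1}")
    return ConfusionCounts(
        Tp=int(np.sum((t == CLASS1) & (p == CLASS1))),
        Tn=int(np.sum((t == CLASS0) & (p == CLASS0))),
        Fp=int(np.sum((t == CLASS0) & (p == CLASS1))),
        Fn=int(np.sum((t == CLASS1) & (p == CLASS0))),
    )


def roc_auc(true_labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve, thresholds at unique scores.

    Constant scores give 0.5; perfectly separating scores give 1.0.
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D sequences")
    n_pos = int(np.sum(y == CLASS1))
    n_neg = int(np.sum(y == CLASS0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one sample of each class")
    order = np.argsort(-s, kind="mergesort")
    y_sorted, s_sorted = y[order], s[order]
    # indices where the threshold changes (end of each tie group)
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y_sorted == CLASS1)[idx]
    fps = np.cumsum(y_sorted == CLASS0)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    counts: ConfusionCounts,
    scores: Sequence[float] | None = None,
    true_labels: Sequence[int] | None = None,
    weights_tag: str = "",
    test_set_tag: str = "",
) -> MetricsRecord:
    """Accuracy/precision/recall/F1 from counts; AUC from scores if given.

    Also reports macro-averaged precision/recall/F1 (means over the two
    one-vs-rest views) for comparison with per-positive-class values.
    """
    if counts.n == 0:
        raise ValueError("cannot compute metrics on zero samples")
    degenerate: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (counts.Tp + counts.Tn) / counts.n
    precision = _ratio(counts.Tp, counts.Tp + counts.Fp, "precision")
    recall = _ratio(counts.Tp, counts.Tp + counts.Fn, "recall")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else (degenerate.append("f1") or 0.0)
    )

    # macro view: the negative class as "positive" swaps Tp<->Tn, Fp<->Fn
    prec0 = counts.Tn / (counts.Tn + counts.Fn) if (counts.Tn + counts.Fn) else 0.0
    rec0 = counts.Tn / (counts.Tn + counts.Fp) if (counts.Tn + counts.Fp) else 0.0
    f1_0 = 2 * prec0 * rec0 / (prec0 + rec0) if (prec0 + rec0) > 0 else 0.0

    if scores is not None:
        if true_labels is None:
            raise ValueError("true_labels are required alongside scores for AUC")
        auc = roc_auc(true_labels, scores)
    else:
        degenerate.append("auc")
        auc = 0.0

    return MetricsRecord(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        n_samples=counts.n,
        weights_tag=weights_tag,
        test_set_tag=test_set_tag,
        degenerate=tuple(degenerate),
        macro_precision=(precision + prec0) / 2,
        macro_recall=(recall + rec0) / 2,
        macro_f1=(f1 + f1_0) / 2,
    )


def build_combined_test(
    test_A: Sequence[ImageSample], test_B: Sequence[ImageSample]
) -> list[ImageSample]:
    """Concatenate two fully-labeled test sets (pooled evaluation, no
    re-weighting); per-sample ``domain_id`` is preserved."""
    for s in list(test_A) + list(test_B):
        if s.label not in (CLASS0, CLASS1):
            raise ConfigurationError(f"test sample {s.sample_id} is not labeled")
    return list(test_A) + list(test_B)


def evaluate_classifier(
    state, test_samples: Sequence[ImageSample], test_set_tag: str,
    threshold: float = 0.5,
) -> MetricsRecord:
    """Predict on a test set and compute the full metrics record."""
    from .classifier import predict_proba

    scores = predict_proba(state, test_samples)
    y_true = labels_of(test_samples)
    y_pred = np.where(scores >= threshold, CLASS1, CLASS0)
    counts = confusion_counts(y_true, y_pred)
    return compute_metrics(
        counts,
        scores=scores,
        true_labels=y_true,
        weights_tag=state.weights_tag,
        test_set_tag=test_set_tag,
    )


def evaluate_matrix(
    classifiers: Mapping[str, object],
    test_sets: Mapping[str, Sequence[ImageSample]],
) -> pd.DataFrame:
    """One metrics row per (weights_tag, test_set_tag) pair, as a tidy table."""
    rows = []
    for wtag, state in classifiers.items():
        for ttag, samples in test_sets.items():
            rec = evaluate_classifier(state, samples, test_set_tag=ttag)
            rows.append(
                {
                    "weights_tag": wtag,
                    "test_set_tag": ttag,
                    "accuracy": rec.accuracy,
                    "precision": rec.precision,
                    "recall": rec.recall,
                    "f1": rec.f1,
                    "auc": rec.auc,
                    "n_samples": rec.n_samples,
                    "degenerate": ";".join(rec.degenerate),
                }
            )
    return pd.DataFrame(rows)
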