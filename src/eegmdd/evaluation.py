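"""Confusion-matrix metrics, hold-out evaluation with a data-leakage guard,
frontal alpha asymmetry, and two-sample group comparisons.

MDD is the positive class throughout.  On a balanced test set the accuracy
equals the average of sensitivity and specificity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classifiers import LabeledDataset, POSITIVE, NEGATIVE


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    accuracy: float     # percent
    sensitivity: float  # percent, true-positive rate on MDD
    specificity: float  # percent, true-negative rate on HC


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity and specificity in percent."""
    if c.total == 0:
        raise ValueError("empty test set")
    if c.tp + c.fn == 0:
        raise ValueError("no positive (MDD) test subjects: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no negative (HC) test subjects: specificity undefined")
    return Metrics(
        accuracy=100.0 * (c.tp + c.tn) / c.total,
        sensitivity=100.0 * c.tp / (c.tp + c.fn),
        specificity=100.0 * c.tn / (c.tn + c.fp),
    )


def evaluate_holdout(model, test: LabeledDataset) -> tuple[ConfusionCounts, Metrics]:
    """Predict each test subject once and report counts and metrics.

    If the model carries ``train_subject_ids`` and the test set carries
    subject ids, any overlap aborts the evaluation: a test subject that was
    seen in training would leak information and inflate the estimate.
    """
    train_ids = getattr(model, "train_subject_ids", None)
    if train_ids is not None and test.subject_ids is not None:
        overlap = sorted(set(train_ids) & set(test.subject_ids))
        if overlap:
            raise ValueError(
                f"data leakage: test subjects also present in training: {overlap}"
            )
    pred = np.asarray(model.predict(test.X))
    y = test.y
    counts = ConfusionCounts(
        tp=int(np.sum((pred == POSITIVE) & (y == POSITIVE))),
        fn=int(np.sum((pred == NEGATIVE) & (y == POSITIVE))),
        tn=int(np.sum((pred == NEGATIVE) & (y == NEGATIVE))),
        fp=int(np.sum((pred == POSITIVE) & (y == NEGATIVE))),
    )
    return counts, confusion_metrics(counts)


def frontal_alpha_asymmetry(alpha_f3: float, alpha_f4: float) -> float:
    """FAA = (F4 - F3) / (F4 + F3) of raw (non-log) alpha band powers,
    bounded in [-1, 1] for non-negative powers."""
    if alpha_f3 < 0 or alpha_f4 < 0:
        raise ValueError("alpha powers must be non-negative (raw, not log)")
    denom = alpha_f3 + alpha_f4
    if denom == 0:
        raise ValueError("FAA undefined: zero total alpha power")
    return (alpha_f4 - alpha_f3) / denom


def faa_from_feature_table(table) -> np.ndarray:
    """Per-subject FAA computed from a feature table's log alpha band powers
    at F3 and F4 (the logs are inverted back to raw power first)."""
    cols = {str(d): i for i, d in enumerate(table.descriptors)}
    try:
        i3, i4 = cols["BP|alpha|F3"], cols["BP|alpha|F4"]
    except KeyError:
        raise ValueError("table lacks alpha band powers at F3/F4") from None
    p3 = 10.0 ** table.values[:, i3]
    p4 = 10.0 ** table.values[:, i4]
    return (p4 - p3) / (p4 + p3)


def group_ttest(values: np.ndarray, labels: "np.ndarray | list") -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance), two-sided.

    ``labels`` may be +1/-1 or 'MDD'/'HC'; the t statistic is oriented as
    (mean MDD - mean HC).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        pos = labels == POSITIVE
        neg = labels == NEGATIVE
    else:
        pos = labels == "MDD"
        neg = labels == "HC"
    a, b = values[pos], values[neg]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two subjects per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cohens_d(values: np.ndarray, labels) -> float:
    """Cohen's d with pooled standard deviation, oriented MDD minus HC."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        a, b = values[labels == POSITIVE], values[labels == NEGATIVE]
    else:
        a, b = values[labels == "MDD"], values[labels == "HC"]
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((np.mean(a) - np.mean(b)) / pooled)
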