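"""Interpretation scores, thresholding, and the eight-metric panel.

The interpretation score of a variant is the softmax probability of the
oncogenic class given the discriminator's two logits; a variant is called
oncogenic when its score strictly exceeds the cutoff (default 0.5).  The
panel comprises accuracy, precision, sensitivity (recall), specificity,
F1, Matthews correlation coefficient, ROC-AUC and PR-AUC.

MCC uses the standard numerator TP*TN - FP*FN with the standard
denominator.  Ratios with a zero denominator are reported as NaN with a
warning rather than silently coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

__all__ = [
    "DEFAULT_CUTOFFS",
    "ConfusionCounts",
    "MetricReport",
    "interpretation_scores",
    "classify",
    "confusion_counts",
    "binary_metrics",
    "roc_auc",
    "pr_auc",
    "evaluate",
    "threshold_sweep",
]

# the published sweep grid: 0.1 .. 0.9 in steps of 0.1, plus 0.95
DEFAULT_CUTOFFS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    roc_auc: float
    pr_auc: float
    cutoff: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def interpretation_scores(model, encoded) -> np.ndarray:
    """Per-variant oncogenicity probability, networks in evaluation mode.

    ``model`` is anything exposing ``predict_proba(matrix) -> (n, 2)`` with
    column 1 the oncogenic class (the trained SGAN model does); ``encoded``
    is an EncodedMatrix or a bare (n, d) array.
    """
    cols = getattr(encoded, "columns", None)
    model_cols = getattr(model, "columns", None)
    if cols is not None and model_cols is not None and list(cols) != list(model_cols):
        raise ValueError("matrix column manifest does not match the model's")
    matrix = getattr(encoded, "matrix", encoded)
    return model.predict_proba(matrix)[:, 1]


def classify(scores: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Oncogenic call iff score strictly greater than the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    return np.asarray(scores) > cutoff


def confusion_counts(calls: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth must be binary (0 benign / 1 oncogenic); "
                         "unlabeled entries are not allowed")
    truth = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(calls & truth)),
        fp=int(np.sum(calls & ~truth)),
        tn=int(np.sum(~calls & ~truth)),
        fn=int(np.sum(~calls & truth)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      UserWarning, stacklevel=3)
        return math.nan
    return num / den


def binary_metrics(c: ConfusionCounts, cutoff: float = 0.5) -> MetricReport:
    """The six threshold-dependent metrics from a confusion matrix."""
    if min(c.tp, c.fp, c.tn, c.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated examples")
    accuracy = (c.tp + c.tn) / c.total
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    if math.isnan(precision) or math.isnan(sensitivity) or (precision + sensitivity) == 0:
        warnings.warn("F1 undefined; reporting NaN", UserWarning, stacklevel=2)
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    denom = ((c.tn + c.fn) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp))
    if denom == 0:
        warnings.warn("MCC undefined (zero denominator); reporting NaN",
                      UserWarning, stacklevel=2)
        mcc = math.nan
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricReport(accuracy=accuracy, precision=precision,
                        sensitivity=sensitivity, specificity=specificity,
                        f1=f1, mcc=mcc, roc_auc=math.nan, pr_auc=math.nan,
                        cutoff=cutoff)


def _check_both_classes(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth)
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth must be binary")
    if truth.min() == truth.max():
        raise ValueError("both classes must be present")
    return truth.astype(bool)


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic; ties count one half."""
    truth = _check_both_classes(truth)
    scores = np.asarray(scores, dtype=np.float64)
    ranks = rankdata(scores)  # average ranks handle ties
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise summation."""
    truth = _check_both_classes(truth)
    return float(average_precision_score(truth, np.asarray(scores, dtype=np.float64)))


def evaluate(scores: np.ndarray, truth: np.ndarray,
             cutoff: float = 0.5) -> MetricReport:
    """Full eight-metric panel at one cutoff."""
    counts = confusion_counts(classify(scores, cutoff), truth)
    report = binary_metrics(counts, cutoff=cutoff)
    report.roc_auc = roc_auc(scores, truth)
    report.pr_auc = pr_auc(scores, truth)
    return report


def threshold_sweep(scores: np.ndarray, truth: np.ndarray,
                    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS) -> pd.DataFrame:
    """One MetricReport row per cutoff; the AUCs repeat across rows."""
    cutoffs = tuple(cutoffs)
    if any(b < a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted ascending")
    rows = [evaluate(scores, truth, cutoff=c).to_dict() for c in cutoffs]
    return pd.DataFrame(rows)
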