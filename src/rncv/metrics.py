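"""The eight evaluation metrics, confusion matrices, and normalisation.

Seven metrics are computed from a 2x2 confusion matrix — accuracy (ACC),
balanced accuracy (BA), precision, recall, F1, Matthews correlation
coefficient (MCC), and Cohen's kappa — while AUC requires continuous ranking
scores and is computed with the Mann-Whitney formulation (mid-rank ties).

Two conventions matter for permutation testing and degenerate folds:

* Zero-denominator convention: precision, recall, F1, MCC and kappa return
  0 whenever a required denominator vanishes (e.g. a constant prediction
  drives the MCC to zero rather than NaN).  This keeps permuted-label scores
  defined on every fold.
* Normalisation: MCC and kappa live on [-1, 1]; :func:`normalise` maps them
  to [0, 1] via ``(x + 1) / 2`` so that scores are comparable across metrics.
  All other metrics already live on [0, 1] and pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .exceptions import RncvError, UndefinedAUCError

__all__ = [
    "ConfusionMatrix",
    "METRIC_IDS",
    "confusion",
    "score",
    "auc",
    "normalise",
    "average_confusions",
]

#: Metric identifiers accepted throughout the package and on the CLI.
METRIC_IDS = ("acc", "ba", "precision", "recall", "f1", "mcc", "kappa", "auc")

#: Metrics whose natural range is [-1, 1] rather than [0, 1].
_SIGNED = frozenset({"mcc", "kappa"})


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix with real-valued entries.

    Entries are reals, not integers, because matrices averaged over folds and
    repeats have fractional entries.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise RncvError("confusion-matrix entries must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred, positive_class) -> ConfusionMatrix:
    """Count the confusion matrix with ``positive_class`` as the positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise RncvError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    t = y_true == positive_class
    p = y_pred == positive_class
    tp = int(np.count_nonzero(t & p))
    fp = int(np.count_nonzero(~t & p))
    fn = int(np.count_nonzero(t & ~p))
    tn = int(np.count_nonzero(~t & ~p))
    return ConfusionMatrix(tp, fp, fn, tn)


def _acc(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def _recall(cm: ConfusionMatrix) -> float:
    d = cm.tp + cm.fn
    return cm.tp / d if d > 0 else 0.0


def _precision(cm: ConfusionMatrix) -> float:
    d = cm.tp + cm.fp
    return cm.tp / d if d > 0 else 0.0


def _ba(cm: ConfusionMatrix) -> float:
    tnr = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else 0.0
    return (_recall(cm) + tnr) / 2.0


def _f1(cm: ConfusionMatrix) -> float:
    d = 2 * cm.tp + cm.fp + cm.fn
    return 2 * cm.tp / d if d > 0 else 0.0


def _mcc(cm: ConfusionMatrix) -> float:
    d = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if d == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(d)


def _kappa(cm: ConfusionMatrix) -> float:
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


_SCORERS = {
    "acc": _acc,
    "ba": _ba,
    "precision": _precision,
    "recall": _recall,
    "f1": _f1,
    "mcc": _mcc,
    "kappa": _kappa,
}


def score(metric: str, cm: ConfusionMatrix) -> float:
    """Evaluate a confusion-matrix metric (every metric except ``auc``)."""
    if metric == "auc":
        raise RncvError("auc needs continuous scores; use rncv.metrics.auc")
    if metric not in _SCORERS:
        raise RncvError(f"unknown metric {metric!r}; choose from {METRIC_IDS}")
    if cm.total <= 0:
        raise RncvError("cannot score an empty confusion matrix")
    return float(_SCORERS[metric](cm))


def auc(y_true, y_score, positive_class) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    ``y_score`` are continuous ranking scores with higher values indicating
    the positive class; ties receive mid-ranks (all-tied scores give 0.5).
    Raises :class:`UndefinedAUCError` when one class is absent — stratified
    folds are the caller's tool for preventing that.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    if y_true.shape != y_score.shape:
        raise RncvError("y_true and y_score must have equal length")
    pos = y_true == positive_class
    n_pos = int(np.count_nonzero(pos))
    n_neg = y_true.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present to compute AUC")
    ranks = rankdata(y_score)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def normalise(metric: str, value: float) -> float:
    """Map a metric value onto [0, 1]; identity except for MCC and kappa."""
    if metric in _SIGNED:
        if not -1.0 <= value <= 1.0:
            raise RncvError(f"{metric} value {value} outside [-1, 1]")
        return (value + 1.0) / 2.0
    if not 0.0 <= value <= 1.0:
        raise RncvError(f"{metric} value {value} outside [0, 1]")
    return float(value)


def average_confusions(cms: Sequence[ConfusionMatrix] | Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Entry-wise arithmetic mean of confusion matrices (fractional entries)."""
    cms = list(cms)
    if not cms:
        raise RncvError("cannot average an empty list of confusion matrices")
    k = len(cms)
    return ConfusionMatrix(
        tp=sum(c.tp for c in cms) / k,
        fp=sum(c.fp for c in cms) / k,
        fn=sum(c.fn for c in cms) / k,
        tn=sum(c.tn for c in cms) / k,
    )
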