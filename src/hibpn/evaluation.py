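"""Classification metrics and relative-gap arithmetic.

Accuracy, F1 and ROC/AUC are the metrics used throughout: the
exclusion/acceptance classes are imbalanced in general, so accuracy
alone can be dominated by the majority class and F1/AUC carry the
discriminative story.  AUC uses the Mann–Whitney convention (ties
credited one half), which makes trapezoidal integration of the ROC
curve and concordant-pair counting agree exactly.

``relative_gap`` reproduces the percentage-drop arithmetic used when
comparing models or ablated variants: 100*(reference - value)/denom,
where the denominator is either the reference (the usual reading) or
the degraded value itself (used by some accuracy-drop figures); both
modes are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "MetricsRow",
    "MetricsReport",
    "accuracy",
    "f1_score",
    "roc_and_auc",
    "relative_gap",
    "min_margin_across_metrics",
]


def _check_binary(labels: np.ndarray, name: str) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")


def accuracy(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    y, yhat = np.asarray(labels), np.asarray(predictions)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    _check_binary(y, "labels")
    _check_binary(yhat, "predictions")
    return float(_skm.accuracy_score(y, yhat))


def f1_score(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """Harmonic mean of precision and recall for the positive class.

    Defined as 0 (with a warning) when there are no true or predicted
    positives at all.
    """
    y, yhat = np.asarray(labels), np.asarray(predictions)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    _check_binary(y, "labels")
    _check_binary(yhat, "predictions")
    if y.sum() == 0 and yhat.sum() == 0:
        warnings.warn("no true or predicted positives; F1 defined as 0", stacklevel=2)
        return 0.0
    return float(_skm.f1_score(y, yhat, zero_division=0))


def roc_and_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) over all score thresholds and the AUC.

    AUC is the area under the curve by trapezoidal integration, equal
    to the Mann–Whitney concordant-pair statistic with ties counted
    one half.  Both classes must be present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    _check_binary(y, "labels")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    auc = float(_skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def relative_gap(
    reference: float,
    value: float,
    denominator_mode: Literal["reference", "value"] = "reference",
) -> float:
    """Percentage drop from ``reference`` to ``value``.

    ``100 * (reference - value) / denominator`` with the denominator
    chosen by mode: the reference (default) or the degraded value
    itself.
    """
    if denominator_mode not in ("reference", "value"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    denom = reference if denominator_mode == "reference" else value
    if denom == 0:
        raise ValueError("zero denominator in relative gap")
    return 100.0 * (reference - value) / denom


@dataclass
class MetricsRow:
    """One model's metrics on one chain."""

    model: str
    chain: str
    acc: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    n_test: int = 0
    positive_class: str = ""

    def as_dict(self) -> dict:
        return {
            "model": self.model, "chain": self.chain,
            "acc": self.acc, "f1": self.f1, "auc": self.auc,
            "n_test": self.n_test, "positive_class": self.positive_class,
        }


@dataclass
class MetricsReport:
    """A stack of metric rows (the model-comparison table shape)."""

    rows: list[MetricsRow] = field(default_factory=list)

    def row(self, model: str, chain: str) -> MetricsRow:
        for r in self.rows:
            if r.model == model and r.chain == chain:
                return r
        raise KeyError(f"no row for model={model!r} chain={chain!r}")


def min_margin_across_metrics(
    hibpn_metrics: Mapping[str, float],
    baseline_table: Mapping[str, Mapping[str, float]],
) -> float:
    """Minimum percentage lead of the network over the best baseline.

    For each of ACC, AUC and F1 the gap is
    ``100 * (hibpn - best_baseline) / hibpn``; the minimum over the
    three metrics is returned (the "outperforms by more than X%"
    figure).
    """
    if not baseline_table:
        raise ValueError("need at least one baseline")
    gaps = []
    for metric in ("acc", "auc", "f1"):
        if metric not in hibpn_metrics:
            raise ValueError(f"missing metric {metric!r} for the network")
        best = -np.inf
        for name, row in baseline_table.items():
            if metric not in row:
                raise ValueError(f"missing metric {metric!r} for baseline {name!r}")
            best = max(best, row[metric])
        gaps.append(relative_gap(hibpn_metrics[metric], best, "reference"))
    return min(gaps)
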