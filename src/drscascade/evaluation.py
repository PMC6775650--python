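"""Classification metrics: one-vs-all confusion counts, MCC, rates, ROC.

Every multi-class result is scored as a set of binary one-vs-all problems.
The Matthews correlation coefficient (MCC) is the primary summary because
the tissue classes are heavily imbalanced; it is computed from the 2x2
counts as

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with value +1 for a perfect classification, -1 for a complete reversal and
0 for chance-level output.  When any factor under the root is zero the
conventional value 0 is returned.

:func:`metrics_report` aggregates cross-validation predictions: metrics are
computed per repeat, then reported as mean and standard deviation across
repeats, at both the individual-spectrum and the per-location level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import CountError, InputError, RocError

CLASSES = ("fat", "wall", "tumor")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 one-vs-all table: TP, TN, FP, FN."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise CountError("confusion counts must be non-negative")
        if self.total == 0:
            raise CountError("confusion table must contain at least one item")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    predictions: Sequence, truths: Sequence, positive_class
) -> ConfusionCounts:
    """Reduce label lists to the 2x2 one-vs-all table for ``positive_class``."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size == 0 or truths.size == 0:
        raise CountError("empty label lists")
    if predictions.shape != truths.shape:
        raise InputError("predictions and truths must have equal length")
    pred_pos = predictions == positive_class
    true_pos = truths == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a 2x2 table; 0 on zero denominators."""
    num = c.tp * c.tn - c.fp * c.fn
    factors = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if any(f == 0 for f in factors):
        return 0.0
    return num / math.sqrt(math.prod(float(f) for f in factors))


@dataclass(frozen=True)
class BasicRates:
    """Accuracy, sensitivity, specificity; None when the denominator is empty."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]


def basic_rates(c: ConfusionCounts) -> BasicRates:
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return BasicRates(accuracy, sensitivity, specificity)


def weighted_accuracy(
    per_class_accuracy: Mapping[str, float], per_class_counts: Mapping[str, int]
) -> float:
    """Mean of per-class accuracies weighted by per-class item counts."""
    if set(per_class_accuracy) != set(per_class_counts):
        raise InputError("accuracy and count maps must share keys")
    if not per_class_counts or any(n <= 0 for n in per_class_counts.values()):
        raise InputError("counts must be positive")
    total = sum(per_class_counts.values())
    return sum(per_class_accuracy[k] * per_class_counts[k] for k in per_class_counts) / total


def roc(scores: Sequence[float], binary_truths: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve from a full threshold sweep, plus trapezoid AUC.

    ``binary_truths`` may be bools or 0/1.  The curve is anchored at (0, 0)
    and (1, 1).  Returns (fpr, tpr, thresholds, auc).
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(binary_truths).astype(bool)
    if truths.all() or not truths.any():
        raise RocError("both classes must be present to sweep an ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(truths.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def _per_class_scores(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """One-vs-all monotone scores per class derived from the cascade scores.

    fat: stage-1 score; tumor: the cascade tumor score (non-fat AND tumor
    side of stage 2); wall: non-fat AND wall side of stage 2.
    """
    s_fat = frame["score_fat"].to_numpy()
    stage2 = frame["stage2_score"].to_numpy()
    return {
        "fat": s_fat,
        "tumor": frame["tumor_score"].to_numpy(),
        "wall": np.minimum(-s_fat, -stage2),
    }


@dataclass
class MetricsReport:
    """Across-repeat summary of a cross-validated run.

    ``per_class`` maps class -> {metric -> (mean, sd)} plus per-class item
    counts; computed at the spectrum level and again per location (majority
    vote).  ``roc_points`` holds one (fpr, tpr, auc) sweep per class from a
    single repeat, mirroring how such curves are usually reported.
    """

    per_class: dict
    weighted_accuracy: tuple[float, float]
    per_class_location: dict
    weighted_accuracy_location: tuple[float, float]
    roc_points: dict

    def to_dict(self) -> dict:
        def pack(block):
            return {
                cls: {
                    metric: {"mean": v[0], "sd": v[1]} if isinstance(v, tuple) else v
                    for metric, v in metrics.items()
                }
                for cls, metrics in block.items()
            }

        return {
            "per_class": pack(self.per_class),
            "weighted_accuracy": {
                "mean": self.weighted_accuracy[0],
                "sd": self.weighted_accuracy[1],
            },
            "per_class_location": pack(self.per_class_location),
            "weighted_accuracy_location": {
                "mean": self.weighted_accuracy_location[0],
                "sd": self.weighted_accuracy_location[1],
            },
            "roc": {
                cls: {"fpr": list(map(float, f)), "tpr": list(map(float, t)), "auc": a}
                for cls, (f, t, a) in self.roc_points.items()
            },
        }


def _repeat_metrics(frame: pd.DataFrame, classes: Sequence[str]) -> tuple[dict, float]:
    per_class = {}
    counts = {}
    for cls in classes:
        c = confusion(frame["predicted_class"], frame["true_class"], cls)
        rates = basic_rates(c)
        per_class[cls] = {
            "accuracy": rates.accuracy,
            "mcc": mcc(c),
            "sensitivity": rates.sensitivity,
            "specificity": rates.specificity,
        }
        counts[cls] = int((frame["true_class"] == cls).sum())
    weighted = weighted_accuracy(
        {cls: per_class[cls]["accuracy"] for cls in classes}, counts
    )
    return per_class, weighted


def _aggregate(frames_by_repeat, classes):
    rows = {cls: {m: [] for m in ("accuracy", "mcc", "sensitivity", "specificity")} for cls in classes}
    weighted = []
    n_items = None
    for frame in frames_by_repeat:
        per_class, w = _repeat_metrics(frame, classes)
        weighted.append(w)
        n_items = len(frame)
        for cls in classes:
            for metric, value in per_class[cls].items():
                if value is not None:
                    rows[cls][metric].append(value)
    summary = {
        cls: {
            metric: (float(np.mean(vals)), float(np.std(vals, ddof=0)))
            for metric, vals in metrics.items()
            if vals
        }
        for cls, metrics in rows.items()
    }
    for cls in classes:
        summary[cls]["n"] = n_items
    return summary, (float(np.mean(weighted)), float(np.std(weighted, ddof=0)))


def metrics_report(
    predictions: pd.DataFrame,
    classes: Sequence[str] = CLASSES,
    roc_repeat: int = 0,
) -> MetricsReport:
    """Summarize cross-validation predictions across repeats.

    ``predictions`` is the frame produced by
    :func:`drscascade.cascade.cross_validate`.
    """
    from .cascade import location_predictions  # local import avoids a cycle

    by_repeat = [g for _, g in predictions.groupby("repeat", sort=True)]
    per_class, weighted = _aggregate(by_repeat, classes)
    loc = location_predictions(predictions)
    loc_by_repeat = [g for _, g in loc.groupby("repeat", sort=True)]
    per_class_loc, weighted_loc = _aggregate(loc_by_repeat, classes)

    roc_frame = predictions[predictions["repeat"] == roc_repeat]
    scores = _per_class_scores(roc_frame)
    roc_points = {}
    for cls in classes:
        truths = (roc_frame["true_class"] == cls).to_numpy()
        fpr, tpr, _, auc = roc(scores[cls], truths)
        roc_points[cls] = (fpr, tpr, auc)
    return MetricsReport(
        per_class=per_class,
        weighted_accuracy=weighted,
        per_class_location=per_class_loc,
        weighted_accuracy_location=weighted_loc,
        roc_points=roc_points,
    )
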