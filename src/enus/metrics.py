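"""Confusion-matrix tallies and the six binary-classification metrics.

The minority (disease) class is the positive class throughout. All
metrics are proportions in [0, 1]; percentage formatting belongs to the
reporting layer.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

__all__ = ["ConfusionCounts", "MetricSet", "confusion_counts", "metric_set"]

METRIC_NAMES = ("acc", "bacc", "sen", "spe", "pre", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    bacc: float
    sen: float
    spe: float
    pre: float
    f1: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_percentages(self) -> dict[str, float]:
        return {name: 100.0 * getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(
    truth: Sequence, predicted: Sequence, positive
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the given positive (minority) class."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    if len(truth) == 0:
        raise ValueError("cannot tally an empty label sequence")
    classes = set(truth) | set(predicted)
    if len(classes - {positive}) > 1:
        raise ValueError(f"labels {sorted(map(str, classes))} are not binary "
                         f"with positive={positive!r}")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    # zero-denominator convention: undefined rates are reported as 0
    return num / den if den > 0 else 0.0


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Accuracy, balanced accuracy, sensitivity, specificity, precision, F1.

    acc = (TP+TN)/(P+N); bacc = (TPR+TNR)/2; sen = TP/(TP+FN);
    spe = TN/(TN+FP); pre = TP/(TP+FP); f1 = 2*pre*sen/(pre+sen).
    """
    if c.total < 1:
        raise ValueError("confusion counts are all zero")
    sen = _ratio(c.tp, c.tp + c.fn)
    spe = _ratio(c.tn, c.tn + c.fp)
    pre = _ratio(c.tp, c.tp + c.fp)
    return MetricSet(
        acc=(c.tp + c.tn) / c.total,
        bacc=(sen + spe) / 2.0,
        sen=sen,
        spe=spe,
        pre=pre,
        f1=_ratio(2.0 * pre * sen, pre + sen),
    )
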