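"""Classification metrics for benchmark evaluation.

Predicted differential-connectivity calls (edges, genes, or pathways) are
compared against ground-truth labels with six measures: sensitivity,
specificity, true discovery rate (TDR, precision), true non-discovery rate
(TNDR, negative predictive value), F1 (harmonic mean of sensitivity and
TDR), and the Matthews correlation coefficient. Ratios with a zero
denominator are reported as 0 and flagged, so aggregation over replicates
never propagates NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ConfusionCounts", "PerformanceReport", "confusion", "performance"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: float
    specificity: float
    tdr: float
    tndr: float
    f1: float
    mcc: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tdr": self.tdr,
            "tndr": self.tndr,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def confusion(predicted: dict, truth: dict) -> ConfusionCounts:
    """2x2 counts over a shared hypothesis universe (hypothesis -> bool)."""
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must cover the same hypotheses")
    tp = tn = fp = fn = 0
    for h, pred in predicted.items():
        if pred and truth[h]:
            tp += 1
        elif pred and not truth[h]:
            fp += 1
        elif not pred and truth[h]:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def performance(c: ConfusionCounts) -> PerformanceReport:
    """The six benchmark measures; zero-denominator ratios become 0 and are
    listed in ``undefined``."""
    und: set[str] = set()
    sens = _ratio(c.TP, c.TP + c.FN, "sensitivity", und)
    spec = _ratio(c.TN, c.TN + c.FP, "specificity", und)
    tdr = _ratio(c.TP, c.TP + c.FP, "tdr", und)
    tndr = _ratio(c.TN, c.TN + c.FN, "tndr", und)
    if sens > 0 and tdr > 0:
        f1 = 2.0 / (1.0 / sens + 1.0 / tdr)
    else:
        und.add("f1")
        f1 = 0.0
    denom = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        und.add("mcc")
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / denom
    return PerformanceReport(sens, spec, tdr, tndr, f1, mcc, frozenset(und))
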