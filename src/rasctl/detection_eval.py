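"""Detection-metric formulas and macro aggregation for the behavior detector.

Per class: P = TP/(TP+FP)·100, R = TP/(TP+FN)·100, F1 = 2PR/(P+R); AP values
are supplied externally (computing AP needs ranked detections, which are out
of scope here).  The overall report averages mAP/P/R arithmetically over
classes, and — deliberately — averages the *per-class F1 values* rather than
taking the harmonic mean of the averaged P and R; only that convention
reproduces the published overall F1.  Undefined metrics (zero denominators)
are reported as NaN and flagged, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["ClassCounts", "ClassMetrics", "MacroReport", "precision_recall", "f1", "macro_report"]


@dataclass(frozen=True)
class ClassCounts:
    """Raw confusion counts for one behavior class; AP in percent."""

    name: str
    tp: int
    fp: int
    fn: int
    ap: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError(f"{self.name}: counts must be non-negative")
        if not 0.0 <= self.ap <= 100.0:
            raise ValueError(f"{self.name}: AP must be in [0, 100], got {self.ap}")


@dataclass(frozen=True)
class ClassMetrics:
    """Pre-computed per-class rates (percent)."""

    name: str
    ap: float
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        return f1(self.precision, self.recall)


def precision_recall(counts: ClassCounts) -> tuple[float, float]:
    """(precision %, recall %); NaN where the denominator is zero."""
    p = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else math.nan
    r = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else math.nan
    return p, r


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent); NaN when undefined."""
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MacroReport:
    """Macro-averaged detector report (all values percent)."""

    map: float
    precision: float
    recall: float
    f1: float
    per_class: tuple[ClassMetrics, ...]
    convention: str = "overall F1 = arithmetic mean of per-class F1"

    @property
    def defined(self) -> bool:
        return not any(
            math.isnan(v) for v in (self.map, self.precision, self.recall, self.f1)
        )

    def to_dict(self) -> dict:
        return {
            "overall": {
                "mAP": self.map,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "defined": self.defined,
            },
            "per_class": [
                {
                    "class": c.name,
                    "AP": c.ap,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                }
                for c in self.per_class
            ],
            "convention": self.convention,
        }


def _as_metrics(entry: ClassCounts | ClassMetrics) -> ClassMetrics:
    if isinstance(entry, ClassMetrics):
        return entry
    p, r = precision_recall(entry)
    return ClassMetrics(name=entry.name, ap=entry.ap, precision=p, recall=r)


def macro_report(per_class: Sequence[ClassCounts | ClassMetrics]) -> MacroReport:
    """Aggregate per-class metrics into the overall (mAP, P, R, F1) quadruple."""
    if not per_class:
        raise ValueError("macro_report needs at least one class")
    metrics = tuple(_as_metrics(e) for e in per_class)
    n = len(metrics)
    mean = lambda vals: sum(vals) / n if not any(math.isnan(v) for v in vals) else math.nan  # noqa: E731
    return MacroReport(
        map=mean([m.ap for m in metrics]),
        precision=mean([m.precision for m in metrics]),
        recall=mean([m.recall for m in metrics]),
        f1=mean([m.f1 for m in metrics]),
        per_class=metrics,
    )
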