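"""Confusion-matrix accounting and binary classification measures.

Accuracy, precision, recall and F1 are computed from TP/FP/FN/TN with an
explicit positive class; the per-class report treats each class as positive
in turn and shares one overall accuracy, mirroring the usual two-class
benchmark tables.  Undefined ratios (zero denominators) are reported as 0
with a degeneracy flag rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} contains values outside {{0, 1}}")
    return arr.astype(np.int64)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: int = 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(y_true, y_pred, positive_class: int = 1) -> ConfusionCounts:
    """Standard confusion cells with the stated positive class."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.size} true vs {yp.size} predicted")
    pos = int(positive_class)
    if pos not in (0, 1):
        raise ValueError("positive_class must be 0 or 1")
    t, p = yt == pos, yp == pos
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
        positive_class=pos,
    )


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # some ratio had a zero denominator


def _ratio(num: int, den: int) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy (TP+TN)/n, precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R)."""
    if counts.total < 1:
        raise ValueError("no evaluated pairs")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision, d1 = _ratio(counts.tp, counts.tp + counts.fp)
    recall, d2 = _ratio(counts.tp, counts.tp + counts.fn)
    if precision + recall > 0:
        f1, d3 = 2 * precision * recall / (precision + recall), False
    else:
        f1, d3 = 0.0, True
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1,
                   degenerate=d1 or d2 or d3)


@dataclass
class ClassRow:
    label: int
    precision: float
    recall: float
    f1: float
    support: int
    flagged: bool = False  # class absent from y_true or degenerate ratios


@dataclass
class EvaluationReport:
    """Overall accuracy plus one precision/recall/F1 row per class."""

    accuracy: float
    rows: list[ClassRow] = field(default_factory=list)

    def row(self, label: int) -> ClassRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "A": self.accuracy,
                    "class": r.label,
                    "P": r.precision,
                    "R": r.recall,
                    "F1": r.f1,
                    "support": r.support,
                    "flagged": r.flagged,
                }
                for r in self.rows
            ]
        )

    def to_text(self) -> str:
        """Aligned percentage table: accuracy to 2 d.p., P/R/F1 to the nearest percent."""
        lines = [f"A (%): {100 * self.accuracy:.2f}",
                 f"{'Class':>5} {'P (%)':>6} {'R (%)':>6} {'F1 (%)':>6}"]
        for r in self.rows:
            flag = "  *" if r.flagged else ""
            lines.append(
                f"{r.label:>5} {100 * r.precision:>6.0f} {100 * r.recall:>6.0f} "
                f"{100 * r.f1:>6.0f}{flag}"
            )
        return "\n".join(lines)

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def class_report(y_true, y_pred, classes: Sequence[int] = (0, 1)) -> EvaluationReport:
    """Per-class report: each class is treated as positive in turn.

    A class absent from ``y_true`` gets a flagged row computed from the
    available counts rather than an error.
    """
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.size} true vs {yp.size} predicted")
    accuracy = float(np.mean(yt == yp))
    rows = []
    for cls in classes:
        counts = confusion_counts(yt, yp, positive_class=cls)
        m = compute_metrics(counts)
        support = int(np.sum(yt == cls))
        rows.append(
            ClassRow(
                label=int(cls),
                precision=m.precision,
                recall=m.recall,
                f1=m.f1,
                support=support,
                flagged=support == 0 or m.degenerate,
            )
        )
    return EvaluationReport(accuracy=accuracy, rows=rows)
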