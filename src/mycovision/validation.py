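"""Pixelwise segmentation-accuracy metrics against ground-truth masks.

Given a predicted binary segmentation and a ground-truth binary image of
the same shape, the module computes the confusion counts and the four
standard detection measures — precision, recall, F-measure and Matthews
Correlation Coefficient (MCC) — plus a batch table with a trailing
``Average`` row.  A value of 1 means perfect detection for all four.

Degenerate zero-denominator cases (e.g. an empty prediction) report the
affected metric as 0 rather than NaN so batch tables stay numeric; such
rows are flagged in a ``notes`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import as_binary

__all__ = ["ConfusionCounts", "confusion_counts", "accuracy_metrics", "evaluate_pairs"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts with the ground truth as reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN of a predicted mask against ground truth."""
    p = as_binary(pred)
    t = as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != truth shape {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy_metrics(c: ConfusionCounts) -> Tuple[float, float, float, float]:
    """(precision, recall, F-measure, MCC) from confusion counts.

    precision = tp/(tp+fp); recall = tp/(tp+fn);
    F = 2 P R / (P + R); MCC = (tp tn - fp fn) /
    sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).  Any zero denominator makes the
    affected metric 0 (documented convention).
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return (precision, recall, f, mcc)


def evaluate_pairs(
    pairs: Iterable[Tuple[np.ndarray, np.ndarray]],
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Evaluate (prediction, truth) mask pairs; append an ``Average`` row.

    Returns a DataFrame with columns ``image, precision, recall,
    f_measure, mcc, notes`` — one row per pair plus a trailing row
    labeled ``Average`` holding the column means over the images.
    """
    rows = []
    for i, (pred, truth) in enumerate(pairs):
        name = names[i] if names is not None else f"image_{i + 1}"
        c = confusion_counts(pred, truth)
        p, r, f, m = accuracy_metrics(c)
        degenerate = (c.tp + c.fp) == 0 or (c.tp + c.fn) == 0
        rows.append(
            {
                "image": name,
                "precision": p,
                "recall": r,
                "f_measure": f,
                "mcc": m,
                "notes": "zero-denominator" if degenerate else "",
            }
        )
    df = pd.DataFrame(rows, columns=["image", "precision", "recall", "f_measure", "mcc", "notes"])
    if len(df):
        avg = {
            "image": "Average",
            "precision": df["precision"].mean(),
            "recall": df["recall"].mean(),
            "f_measure": df["f_measure"].mean(),
            "mcc": df["mcc"].mean(),
            "notes": "",
        }
        df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return df
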