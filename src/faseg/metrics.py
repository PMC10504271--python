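"""Confusion-matrix segmentation metrics (Acc, Dice, IoU, Sen, Spec).

Lesion pixels are the positive class.  Definitions:

    Acc  = (TP + TN) / (TP + FP + TN + FN)
    Dice = 2 TP / (2 TP + FP + FN)
    IoU  = TP / (TP + FP + FN)
    Sen  = TP / (TP + FN)
    Spec = TN / (TN + FP)

Zero-denominator convention: when both prediction and ground truth are
empty, Dice/IoU/Sen are 1 (correct rejection); any other metric with a
zero denominator is reported as 0 (and flagged in the report).  Dice and
IoU are algebraically tied: Dice = 2 IoU / (1 + IoU).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import SegmentationMask

METRIC_COLUMNS = ["Acc", "IoU", "Dice", "Sen", "Spec"]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)


def _as_binary(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.pixels.astype(bool)
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be binary")
    return arr.astype(bool)


def confusion(pred, gt) -> ConfusionMatrix:
    """Pixel-wise confusion counts (lesion = positive)."""
    p, g = _as_binary(pred), _as_binary(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionMatrix(tp, fp, fn, tn)


def _ratio(num: int, den: int, empty_is_perfect: bool) -> float:
    if den == 0:
        return 1.0 if empty_is_perfect else 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TP + cm.TN, cm.total, empty_is_perfect=False)


def dice(cm: ConfusionMatrix) -> float:
    return _ratio(2 * cm.TP, 2 * cm.TP + cm.FP + cm.FN, empty_is_perfect=True)


def iou(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TP, cm.TP + cm.FP + cm.FN, empty_is_perfect=True)


def sensitivity(cm: ConfusionMatrix) -> float:
    # empty ground truth with empty prediction counts as a correct rejection
    return _ratio(cm.TP, cm.TP + cm.FN,
                  empty_is_perfect=(cm.FP == 0))


def specificity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TN, cm.TN + cm.FP, empty_is_perfect=(cm.FN == 0))


def metric_row(cm: ConfusionMatrix) -> dict[str, float]:
    return {"Acc": accuracy(cm), "IoU": iou(cm), "Dice": dice(cm),
            "Sen": sensitivity(cm), "Spec": specificity(cm)}


def evaluate(pred_masks, gt_masks, mode: str = "pooled") -> dict[str, float]:
    """Aggregate metrics over aligned mask collections.

    ``pooled`` sums confusion counts over all slices then applies the
    formulas (the headline aggregation); ``per_slice_mean`` averages the
    per-slice metrics.
    """
    preds, gts = list(pred_masks), list(gt_masks)
    if len(preds) != len(gts):
        raise ValueError(f"collection length mismatch: "
                         f"{len(preds)} vs {len(gts)}")
    if not preds:
        raise ValueError("empty collections")
    cms = [confusion(p, g) for p, g in zip(preds, gts)]
    if mode == "pooled":
        total = cms[0]
        for cm in cms[1:]:
            total = total + cm
        return metric_row(total)
    if mode == "per_slice_mean":
        rows = pd.DataFrame([metric_row(cm) for cm in cms])
        return rows.mean().to_dict()
    raise ValueError(f"unknown mode {mode!r}")


def evaluation_report(pred_masks, gt_masks) -> pd.DataFrame:
    """Both aggregations as a tidy frame (one row per mode)."""
    rows = []
    for mode in ("pooled", "per_slice_mean"):
        row = {"mode": mode}
        row.update(evaluate(pred_masks, gt_masks, mode))
        rows.append(row)
    return pd.DataFrame(rows, columns=["mode"] + METRIC_COLUMNS)


def write_report(path: str | Path, report: pd.DataFrame) -> None:
    report.to_csv(path, index=False)
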