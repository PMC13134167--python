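"""Segmentation evaluation: per-class confusion counts and the five
overlap/agreement metrics (IoU, Dice, accuracy, precision, recall).

Each class is scored one-vs-rest on pixel counts.  When a class is absent
from both the prediction and the ground truth, ratio metrics are defined
as 1.0 so that all-background images do not poison dataset averages.
Multi-class summaries are macro averages over foreground classes
(background class 0 excluded); accuracy is also reported over all classes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "iou", "dsc", "accuracy",
           "precision", "recall", "evaluate_pair", "macro_report",
           "write_report_csv"]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel counts; each field is an (n_classes,) array."""
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def confusion(pred_mask, gt_mask, n_classes: int) -> ConfusionCounts:
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    total = pred.size
    tp = np.empty(n_classes, dtype=np.int64)
    fp = np.empty(n_classes, dtype=np.int64)
    fn = np.empty(n_classes, dtype=np.int64)
    for c in range(n_classes):
        p = pred == c
        g = gt == c
        tp[c] = np.count_nonzero(p & g)
        fp[c] = np.count_nonzero(p & ~g)
        fn[c] = np.count_nonzero(~p & g)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num, den):
    """Elementwise num/den with the both-empty convention: 0/0 -> 1."""
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.ones_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def iou(c: ConfusionCounts) -> np.ndarray:
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def dsc(c: ConfusionCounts) -> np.ndarray:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def accuracy(c: ConfusionCounts) -> np.ndarray:
    return _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)


def precision(c: ConfusionCounts) -> np.ndarray:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> np.ndarray:
    return _ratio(c.tp, c.tp + c.fn)


_METRICS = {"iou": iou, "dsc": dsc, "accuracy": accuracy,
            "precision": precision, "recall": recall}


def evaluate_pair(pred_mask, gt_mask, n_classes: int) -> dict:
    """Per-class metric arrays for one prediction/ground-truth pair."""
    c = confusion(pred_mask, gt_mask, n_classes)
    return {name: fn(c) for name, fn in _METRICS.items()}


def macro_report(pred_mask, gt_mask, n_classes: int) -> dict:
    """Macro (unweighted foreground-class mean) scalar summary plus the
    per-class arrays under the key ``per_class``."""
    per = evaluate_pair(pred_mask, gt_mask, n_classes)
    fg = slice(1, None) if n_classes > 1 else slice(None)
    out = {name: float(vals[fg].mean()) for name, vals in per.items()}
    out["per_class"] = per
    return out


def write_report_csv(path, rows: list[dict]):
    """Write one evaluation row per (image, class) plus a macro row each.

    Each input row needs keys ``image`` (identifier), ``pred`` and ``gt``
    (label arrays) and ``n_classes``.
    """
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image", "class", "iou", "dsc", "accuracy",
                     "precision", "recall"])
        for row in rows:
            per = evaluate_pair(row["pred"], row["gt"], row["n_classes"])
            for c in range(row["n_classes"]):
                wr.writerow([row["image"], c] +
                            [f"{per[m][c]:.6f}" for m in _METRICS])
            rep = macro_report(row["pred"], row["gt"], row["n_classes"])
            wr.writerow([row["image"], "macro"] +
                        [f"{rep[m]:.6f}" for m in _METRICS])
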