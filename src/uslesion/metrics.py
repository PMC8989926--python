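"""Detection evaluation: one optional predicted box per image.

A predicted box is a true positive when its Jaccard with the image's truth
box is strictly above the TP bound (default 0.5), otherwise a false
positive; an image that has a truth box but no true-positive prediction
counts one false negative.  True negatives are fixed to zero — an image-level
"correct rejection" is not defined for one-box detection — so

    accuracy  = TP / (TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall).

Ratios with a zero denominator are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import BBox, box_jaccard

__all__ = ["EvalCounts", "EvalReport", "evaluate"]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0 or self.tn != 0:
            raise ValueError("counts must be nonnegative with TN fixed to 0")


@dataclass(frozen=True)
class EvalReport:
    counts: EvalCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    mean_iou: float
    std_iou: float
    per_image_iou: dict[str, float] = field(default_factory=dict)
    undefined: tuple[str, ...] = ()   # ratios whose denominator was zero

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fp": self.counts.fp,
            "fn": self.counts.fn, "tn": self.counts.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "mean_iou": self.mean_iou, "std_iou": self.std_iou,
            "undefined": list(self.undefined),
        }


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def evaluate(preds: Mapping[str, Optional[BBox]],
             truths: Mapping[str, Optional[BBox]],
             tp_bound: float = 0.5) -> EvalReport:
    """Score per-image one-box predictions against per-image truths.

    ``preds`` and ``truths`` map the same image ids to a box or ``None``
    (no detection / normal image); a mismatch of the id sets is an error.
    Mean/std IoU run over images holding both a truth and a prediction.
    """
    if set(preds) != set(truths):
        raise ValueError("prediction and truth image-id sets differ: "
                         f"{sorted(set(preds) ^ set(truths))}")
    tp = fp = fn = 0
    ious: dict[str, float] = {}
    flags: list[str] = []
    for img_id in sorted(preds):
        pred = preds[img_id]
        truth = truths[img_id]
        if truth is not None:
            detected = False
            if pred is not None:
                j = box_jaccard(pred, truth)
                ious[img_id] = j
                if j > tp_bound:
                    tp += 1
                    detected = True
                else:
                    fp += 1
            if not detected:
                fn += 1
        elif pred is not None:
            fp += 1   # detection on a normal image
    accuracy = _ratio(tp, tp + fp + fn, "accuracy", flags)
    precision = _ratio(tp, tp + fp, "precision", flags)
    recall = _ratio(tp, tp + fn, "recall", flags)
    f1 = _ratio(2 * recall * precision, recall + precision, "f1", flags)
    vals = np.array(list(ious.values())) if ious else np.zeros(0)
    return EvalReport(
        counts=EvalCounts(tp=tp, fp=fp, fn=fn),
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        mean_iou=float(vals.mean()) if vals.size else 0.0,
        std_iou=float(vals.std()) if vals.size else 0.0,
        per_image_iou=ious, undefined=tuple(flags))
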