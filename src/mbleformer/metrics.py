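"""Dice+BCE training objective and the seven pixel-level evaluation metrics.

The loss is the unit-weighted sum of a smoothed Dice loss,

    L_dice = 1 - (2 * sum(p*y) + eps) / (sum(p) + sum(y) + eps),

and mean binary cross-entropy with the probabilities clamped away from
{0, 1}.  Evaluation reports recall, specificity, precision, F1, F2, overall
pixel accuracy and mIoU from pooled pixel confusion counts, with lesion as
the positive class.  mIoU averages the foreground IoU TP/(TP+FP+FN) and the
background IoU TN/(TN+FP+FN) by default (a foreground-only variant is a
switch).  Ratios that are 0/0 — an absent class handled perfectly — score 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor

DICE_EPS = 1e-6
BCE_CLAMP = 1e-7

# column names used in report files
REPORT_COLUMNS = ("Recall", "Specificity", "Precision", "F1", "F2",
                  "Acc_overcall", "mIoU")


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def dice_loss(p, y, eps: float = DICE_EPS) -> Tensor:
    """Smoothed soft Dice loss; differentiable in p."""
    p, yt = _lift(p), _lift(y)
    if p.shape != yt.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {yt.shape}")
    inter = (p * yt).sum()
    return 1.0 - (2.0 * inter + eps) / (p.sum() + yt.sum() + eps)


def bce_loss(p, y, clamp: float = BCE_CLAMP) -> Tensor:
    """Mean binary cross-entropy with probability clamping."""
    p, yt = _lift(p), _lift(y)
    if p.shape != yt.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {yt.shape}")
    pc = p.clip(clamp, 1.0 - clamp)
    ll = yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()
    return -ll.mean()


def dice_bce_loss(p, y) -> Tensor:
    """Unit-weighted sum of Dice and BCE losses."""
    return dice_loss(p, y) + bce_loss(p, y)


# ---------------------------------------------------------------------------
# confusion counts and the metric report
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricReport:
    recall: float
    specificity: float
    precision: float
    f1: float
    f2: float
    acc_overall: float
    miou: float

    def to_dict(self) -> dict[str, float]:
        return dict(zip(REPORT_COLUMNS,
                        (self.recall, self.specificity, self.precision,
                         self.f1, self.f2, self.acc_overall, self.miou)))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_csv(self, path: str | Path, label: str = "eval") -> None:
        path = Path(path)
        new = not path.exists()
        with path.open("a", newline="") as fh:
            writer = csv.writer(fh)
            if new:
                writer.writerow(("label",) + REPORT_COLUMNS)
            writer.writerow([label] + [f"{v:.6f}" for v in
                                       self.to_dict().values()])


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixel confusion counts; lesion (1) is the positive class."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    for name, arr in (("pred", pred), ("gt", gt)):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} is not binary; values {vals[:5]}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def _ratio(num: int, den: int) -> float:
    # 0/0: the class is absent and nothing was predicted for it -> perfect
    if den == 0:
        return 1.0
    return num / den


def metric_report(counts: ConfusionCounts,
                  miou_classes: str = "fg+bg") -> MetricReport:
    """Derive the seven evaluation metrics from pixel confusion counts."""
    if min(counts.tp, counts.fp, counts.fn, counts.tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    if precision + recall == 0:
        f1 = f2 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
        f2 = 5 * precision * recall / (4 * precision + recall)
    acc = (tp + tn) / counts.total
    iou_fg = _ratio(tp, tp + fp + fn)
    if miou_classes == "fg":
        miou = iou_fg
    elif miou_classes == "fg+bg":
        iou_bg = _ratio(tn, tn + fp + fn)
        miou = 0.5 * (iou_fg + iou_bg)
    else:
        raise ValueError(f"miou_classes must be 'fg' or 'fg+bg', "
                         f"got {miou_classes!r}")
    return MetricReport(recall, specificity, precision, f1, f2, acc, miou)
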