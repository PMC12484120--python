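"""Dice loss and the five segmentation metrics.

All metrics derive from per-image pixel confusion counts (TP/TN/FP/FN):

    Dice     = 2TP / (2TP + FN + FP)
    Mcc      = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))
    Jaccard  = TP / (TP + FN + FP)
    Accuracy = (TP + TN) / (TP + TN + FN + FP)
    Recall   = TP / (TP + FN)

Degenerate denominators follow the usual conventions: overlap measures are
1 when both masks are empty; Mcc is 0 when any marginal is empty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .nn import functional as F
from .nn.tensor import Tensor

METRIC_NAMES = ("dice", "mcc", "jaccard", "accuracy", "recall")

# Smoothing constant guarding the empty-mask 0/0 case in the Dice loss.
DICE_EPS = 1e-9


def dice_loss(p, y, eps: float = DICE_EPS):
    """Soft Dice loss: 1 - 2*sum(p*y) / (sum(y) + sum(p)).

    ``p`` may be a Tensor (differentiable path used for training) or an
    array; ``y`` is a {0,1} mask of the same extents.  A small ``eps``
    added to numerator and denominator keeps the empty-mask case finite.
    """
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y)
    p_shape = p.shape if isinstance(p, Tensor) else np.asarray(p).shape
    if tuple(p_shape) != tuple(y_arr.shape):
        raise ContractError(f"prediction extents {tuple(p_shape)} != mask extents "
                            f"{tuple(y_arr.shape)}")
    if isinstance(p, Tensor):
        y_t = Tensor(y_arr.astype(p.dtype))
        inter = F.tsum(F.mul(p, y_t))
        denom = F.add(F.tsum(y_t), F.tsum(p))
        return F.sub(1.0, F.div(F.add(F.mul(inter, 2.0), eps), F.add(denom, eps)))
    p_arr = np.asarray(p, dtype=np.float64)
    y64 = y_arr.astype(np.float64)
    return float(1.0 - (2.0 * (p_arr * y64).sum() + eps) / (y64.sum() + p_arr.sum() + eps))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion_counts(pred_mask, y) -> ConfusionCounts:
    """Exact pixel tallies for two binary masks of equal extents."""
    pred_mask = np.asarray(pred_mask)
    y = np.asarray(y)
    if pred_mask.shape != y.shape:
        raise ContractError(f"mask extents differ: {pred_mask.shape} vs {y.shape}")
    for name, arr in (("pred_mask", pred_mask), ("y", y)):
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ContractError(f"{name} is not binary (values {vals[:5]}...)")
    p = pred_mask.astype(bool)
    t = y.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    if c.total < 1:
        raise ContractError("confusion counts cover no pixels")
    tp, tn, fp, fn = (float(v) for v in (c.tp, c.tn, c.fp, c.fn))
    dice = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) > 0 else 1.0
    jaccard = tp / (tp + fn + fp) if (tp + fn + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    accuracy = (tp + tn) / (tp + tn + fn + fp)
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {"dice": dice, "mcc": mcc, "jaccard": jaccard,
            "accuracy": accuracy, "recall": recall}


@dataclass
class MetricReport:
    """Per-image and aggregate values of the five metrics."""

    per_image: pd.DataFrame  # columns: id + METRIC_NAMES
    aggregate: dict[str, float]
    aggregation: str
    n_images: int

    def to_csv(self, path) -> None:
        df = self.per_image.copy()
        agg = {"id": f"aggregate({self.aggregation})", **self.aggregate}
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
        df.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "aggregation": self.aggregation,
            "n_images": self.n_images,
            "aggregate": self.aggregate,
            "per_image": self.per_image.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate(preds, masks, threshold: float = 0.5,
             aggregation: str = "per_image_mean", ids=None) -> MetricReport:
    """Binarize predictions and compute the five metrics per image.

    ``aggregation`` is either ``per_image_mean`` (mean of per-image
    metrics) or ``global_pool`` (metrics of the summed counts).
    """
    preds = np.asarray(preds, dtype=np.float64)
    masks = np.asarray(masks)
    if preds.shape[0] == 0:
        raise ContractError("empty batch")
    if not (0.0 < threshold < 1.0):
        raise ContractError(f"threshold must be in (0, 1), got {threshold}")
    if aggregation not in ("per_image_mean", "global_pool"):
        raise ContractError(f"unknown aggregation {aggregation!r}")
    if preds.shape != masks.shape:
        raise ContractError(f"prediction batch {preds.shape} != mask batch {masks.shape}")
    n = preds.shape[0]
    ids = list(ids) if ids is not None else [f"image_{i:04d}" for i in range(n)]
    rows = []
    counts: list[ConfusionCounts] = []
    for i in range(n):
        c = confusion_counts((preds[i] >= threshold).astype(np.uint8),
                             (masks[i] > 0.5).astype(np.uint8))
        counts.append(c)
        rows.append({"id": ids[i], **metrics_from_counts(c)})
    per_image = pd.DataFrame(rows)
    if aggregation == "per_image_mean":
        aggregate = {m: float(per_image[m].mean()) for m in METRIC_NAMES}
    else:
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        aggregate = metrics_from_counts(pooled)
    return MetricReport(per_image=per_image, aggregate=aggregate,
                        aggregation=aggregation, n_images=n)


def pixel_accuracy(preds, masks, threshold: float = 0.5) -> float:
    """Fraction of pixels whose thresholded prediction matches the mask."""
    preds = np.asarray(preds)
    masks = np.asarray(masks)
    return float(np.mean((preds >= threshold) == (masks > 0.5)))
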