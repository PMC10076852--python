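"""Confusion-matrix evaluation suite for binary segmentation.

All metrics derive from per-image pixel confusion counts:

    IoU       = TP / (TP + FP + FN)
    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    F1        = 2 * Recall * Precision / (Recall + Precision)
    mIoU      = mean of per-image IoU over the evaluation set

Degenerate denominators: when both masks are empty the IoU is defined as
1.0 (a correct empty prediction); all other zero-denominator cases give
0.0 and set ``degenerate=True`` on the counts.  By default the IoU is the
foreground IoU; a two-class (foreground + background) average is
available via ``include_background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts between a predicted and a true mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tabulate TP/FP/FN/TN between two binary masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not np.isin(pred, (0, 1)).all() or not np.isin(truth, (0, 1)).all():
        raise ValueError("masks must be binary (values in {0, 1})")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def iou(c: ConfusionCounts) -> float:
    """Foreground intersection-over-union; 1.0 when both masks are empty."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def background_iou(c: ConfusionCounts) -> float:
    denom = c.tn + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tn / denom


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0.0 when there are no true foreground pixels."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0.0 when nothing was predicted foreground."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def f1(recall_value: float, precision_value: float) -> float:
    """Harmonic mean of recall and precision; 0.0 when both vanish."""
    s = recall_value + precision_value
    return 2.0 * recall_value * precision_value / s if s else 0.0


def miou(per_image_ious) -> float:
    """Arithmetic mean of per-image IoU values."""
    vals = list(per_image_ious)
    if not vals:
        raise ValueError("cannot average an empty IoU list")
    return float(np.mean(vals))


@dataclass
class MetricsReport:
    """Per-image and aggregate metrics, optionally broken down by size class."""

    per_image_iou: list[float]
    miou: float
    recall: float
    precision: float
    f1: float
    n_images: int
    per_category: dict[str, "MetricsReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_images": self.n_images,
            "miou": self.miou,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }
        if self.per_category:
            d["per_category"] = {k: v.to_dict() for k, v in self.per_category.items()}
        return d

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as percentages, one row overall plus one per size class."""
        rows = [{"category": "all", "n": self.n_images,
                 "mIoU/%": 100 * self.miou, "Recall/%": 100 * self.recall,
                 "Precision/%": 100 * self.precision, "F1-score/%": 100 * self.f1}]
        for cat, rep in self.per_category.items():
            rows.append({"category": cat, "n": rep.n_images,
                         "mIoU/%": 100 * rep.miou, "Recall/%": 100 * rep.recall,
                         "Precision/%": 100 * rep.precision, "F1-score/%": 100 * rep.f1})
        return pd.DataFrame(rows)


def report_from_pairs(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    categories: list[str] | None = None,
    include_background: bool = False,
) -> MetricsReport:
    """Build a MetricsReport from (pred, truth) mask pairs.

    Per-image metrics are averaged over the set.  ``categories`` (one
    label per pair, e.g. the dominant lesion size class) enables the
    per-category breakdown.  ``include_background`` switches the IoU to
    the two-class mean of foreground and background IoU.
    """
    if not pairs:
        raise ValueError("empty evaluation set")
    ious, recs, precs, f1s = [], [], [], []
    for pred, truth in pairs:
        c = confusion_counts(pred, truth)
        v = iou(c)
        if include_background:
            v = 0.5 * (v + background_iou(c))
        r, p = recall(c), precision(c)
        ious.append(v)
        recs.append(r)
        precs.append(p)
        f1s.append(f1(r, p))
    report = MetricsReport(
        per_image_iou=ious,
        miou=miou(ious),
        recall=float(np.mean(recs)),
        precision=float(np.mean(precs)),
        f1=float(np.mean(f1s)),
        n_images=len(pairs),
    )
    if categories is not None:
        if len(categories) != len(pairs):
            raise ValueError("one category label per pair required")
        for cat in sorted(set(categories)):
            sub = [pairs[i] for i, c in enumerate(categories) if c == cat]
            report.per_category[cat] = report_from_pairs(sub, include_background=include_background)
    return report
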