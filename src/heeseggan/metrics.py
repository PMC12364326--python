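"""Pixel-level segmentation evaluation (IoU, DSC, SEN, PRE)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "confusion_counts", "segmentation_metrics",
           "evaluate_pair", "aggregate"]


@dataclass
class MetricsReport:
    iou: float
    dsc: float
    sen: float
    pre: float
    counts: tuple[int, int, int, int]  # TP, FP, FN, TN
    n_images: int = 1
    degenerate: bool = False  # empty truth with nonempty prediction

    def as_dict(self) -> dict:
        return {"iou": self.iou, "dsc": self.dsc, "sen": self.sen,
                "pre": self.pre, "n_images": self.n_images}


def confusion_counts(pred_mask: np.ndarray,
                     truth: np.ndarray) -> tuple[int, int, int, int]:
    """Exact (TP, FP, FN, TN) over all pixels."""
    pred_mask = np.asarray(pred_mask)
    truth = np.asarray(truth)
    if pred_mask.shape != truth.shape:
        raise ValueError(f"shapes differ: {pred_mask.shape} vs {truth.shape}")
    for name, arr in (("pred", pred_mask), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred_mask.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return tp, fp, fn, tn


def segmentation_metrics(counts: tuple[int, int, int, int]) -> MetricsReport:
    """IoU/DSC/SEN/PRE from confusion counts.

    Degenerate conventions: an image where truth and prediction are both
    empty scores 1.0 on every metric; empty truth with a nonempty
    prediction reports SEN = 0 and sets the ``degenerate`` flag.
    """
    tp, fp, fn, tn = counts
    if min(counts) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp + fn == 0:  # both empty
        return MetricsReport(1.0, 1.0, 1.0, 1.0, counts)
    degenerate = (tp + fn == 0)
    iou = tp / (tp + fp + fn)
    dsc = 2 * tp / (2 * tp + fp + fn)
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    return MetricsReport(iou, dsc, sen, pre, counts, degenerate=degenerate)


def evaluate_pair(pred_mask: np.ndarray, truth: np.ndarray) -> MetricsReport:
    return segmentation_metrics(confusion_counts(pred_mask, truth))


def aggregate(reports: list[MetricsReport], mode: str = "macro") -> MetricsReport:
    """Dataset aggregation.

    ``macro`` (default) averages per-image metrics; ``micro`` pools the
    confusion counts first.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    counts = tuple(int(sum(r.counts[i] for r in reports)) for i in range(4))
    if mode == "micro":
        out = segmentation_metrics(counts)
        out.n_images = sum(r.n_images for r in reports)
        return out
    if mode != "macro":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    n = len(reports)
    return MetricsReport(
        iou=sum(r.iou for r in reports) / n,
        dsc=sum(r.dsc for r in reports) / n,
        sen=sum(r.sen for r in reports) / n,
        pre=sum(r.pre for r in reports) / n,
        counts=counts,
        n_images=sum(r.n_images for r in reports),
        degenerate=any(r.degenerate for r in reports),
    )
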