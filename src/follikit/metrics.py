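"""Segmentation metrics and their per-image aggregation.

Five pixel-wise scores per image -- accuracy, Dice, IoU, sensitivity,
specificity -- aggregated over a test set as mean +/- population standard
deviation.  Conventions for empty denominators: when ground truth and
prediction are both empty the overlap scores are perfect (1.0); an empty
ground truth with a non-empty prediction scores 0 on Dice/IoU/sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METRIC_NAMES = ("accuracy", "dice", "iou", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    for name, arr in (("gt", gt), ("pred", pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    gt = gt.astype(bool)
    pred = pred.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(gt & pred)),
        fp=int(np.count_nonzero(~gt & pred)),
        fn=int(np.count_nonzero(gt & ~pred)),
        tn=int(np.count_nonzero(~gt & ~pred)),
    )


def _ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den else empty_value


def segmentation_metrics(gt: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    """Accuracy, Dice, IoU, sensitivity, specificity for one mask pair."""
    c = confusion_counts(gt, pred)
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, 1.0),
        "iou": _ratio(c.tp, c.tp + c.fp + c.fn, 1.0),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, 1.0),
        "specificity": _ratio(c.tn, c.tn + c.fp, 1.0),
    }


def aggregate(per_image: list[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Mean and population std per metric over a list of per-image scores."""
    if not per_image:
        raise ValueError("need at least one image to aggregate")
    out = {}
    for name in per_image[0]:
        vals = np.array([scores[name] for scores in per_image], dtype=np.float64)
        out[name] = (float(vals.mean()), float(vals.std()))
    return out


def format_cell(mean: float, std: float, scale: float = 100.0) -> str:
    """Render one aggregate as the conventional 'mm.mm±s.ss' percentage cell."""
    return f"{mean * scale:.2f}±{std * scale:.2f}"
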