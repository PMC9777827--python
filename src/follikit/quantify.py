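"""Follicle sizing, recruitable-range filtering, matching and counting.

A follicle's diameter is the average of its two largest orthogonal diameters.
On a mask this is measured per 8-connected component as the mean of the major
and minor axis lengths of the equivalent ellipse (the ellipse with the same
normalized second central moments), converted to millimetres by the pixel
spacing.  Follicles outside the recruitable range of 2-10 mm are excluded
before counting: below 2 mm small anechoic structures such as vessels could be
miscounted, above 10 mm the follicle is dominant rather than antral.  A
predicted follicle counts as correctly detected when it is matched one-to-one
with a ground-truth follicle at a pairwise Dice strictly greater than 0.5;
precision = correct / detected and recall = correct / real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

RECRUITABLE_LOW_MM = 2.0
RECRUITABLE_HIGH_MM = 10.0
MATCH_DICE_THRESHOLD = 0.5


@dataclass
class FollicleRecord:
    """One connected component of a follicle mask with its morphometry."""

    label: int
    centroid: tuple[float, float]          # (row, col), pixels
    major_axis_px: float
    minor_axis_px: float
    diameter_mm: float
    recruitable: bool
    pixel_set: np.ndarray = field(repr=False)   # boolean mask of the component

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.pixel_set))


@dataclass
class QuantReport:
    n_real: int
    n_detected: int
    n_correct: int
    precision: float
    recall: float
    matches: list[tuple[int, int, float]]   # (gt label, pred label, Dice)
    degenerate: bool = False                # True when a count was zero


def counting_rates(n_correct: int, n_detected: int, n_real: int
                   ) -> tuple[float, float]:
    """Precision and recall (fractions) from follicle counts.

    A zero denominator yields 0 for that rate.
    """
    if not 0 <= n_correct <= min(n_detected, n_real):
        raise ValueError(
            f"inconsistent counts: correct={n_correct}, detected={n_detected}, "
            f"real={n_real}"
        )
    precision = n_correct / n_detected if n_detected else 0.0
    recall = n_correct / n_real if n_real else 0.0
    return precision, recall


def extract_follicles(mask: np.ndarray, pixel_spacing_mm: float,
                      connectivity: int = 2) -> list[FollicleRecord]:
    """Label a binary follicle mask and measure every component.

    ``connectivity=2`` is 8-connectivity (default: follicles are smooth ovals
    and 4-connectivity would split diagonal necks).
    """
    if pixel_spacing_mm <= 0:
        raise ValueError(f"pixel spacing must be positive, got {pixel_spacing_mm}")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    labeled = cc_label(mask > 0, connectivity=connectivity)
    records = []
    for prop in regionprops(labeled):
        major = float(prop.axis_major_length)
        minor = float(prop.axis_minor_length)
        diameter = pixel_spacing_mm * (major + minor) / 2.0
        records.append(FollicleRecord(
            label=int(prop.label),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            major_axis_px=major,
            minor_axis_px=minor,
            diameter_mm=diameter,
            recruitable=RECRUITABLE_LOW_MM <= diameter <= RECRUITABLE_HIGH_MM,
            pixel_set=labeled == prop.label,
        ))
    return records


def recruitable_filter(records: list[FollicleRecord],
                       low: float = RECRUITABLE_LOW_MM,
                       high: float = RECRUITABLE_HIGH_MM
                       ) -> list[FollicleRecord]:
    """Keep follicles with low <= diameter_mm <= high."""
    if low > high:
        raise ValueError(f"low {low} > high {high}")
    return [r for r in records if low <= r.diameter_mm <= high]


def blank_excluded(mask: np.ndarray, records: list[FollicleRecord],
                   kept: list[FollicleRecord]) -> np.ndarray:
    """Zero out the components not in `kept` (the working-mask view of the
    exclusion step)."""
    out = np.asarray(mask).astype(np.uint8).copy()
    kept_labels = {r.label for r in kept}
    for r in records:
        if r.label not in kept_labels:
            out[r.pixel_set] = 0
    return out


def pairwise_dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def match_follicles(gt_records: list[FollicleRecord],
                    pred_records: list[FollicleRecord],
                    dice_threshold: float = MATCH_DICE_THRESHOLD
                    ) -> list[tuple[int, int, float]]:
    """One-to-one greedy matching by descending pairwise Dice.

    Returns (gt label, pred label, Dice) triples with Dice strictly above the
    threshold.  Ties are broken by (gt label, pred label) order so matching is
    deterministic.
    """
    if gt_records and pred_records:
        if gt_records[0].pixel_set.shape != pred_records[0].pixel_set.shape:
            raise ValueError("gt and pred records come from different geometries")
    pairs = []
    for g in gt_records:
        for p in pred_records:
            d = pairwise_dice(g.pixel_set, p.pixel_set)
            if d > dice_threshold:
                pairs.append((d, g.label, p.label))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    matches = []
    for d, gl, pl in pairs:
        if gl in used_gt or pl in used_pred:
            continue
        used_gt.add(gl)
        used_pred.add(pl)
        matches.append((gl, pl, d))
    return matches


def counting_report(gt_mask: np.ndarray, pred_mask: np.ndarray,
                    pixel_spacing_mm: float,
                    low: float = RECRUITABLE_LOW_MM,
                    high: float = RECRUITABLE_HIGH_MM) -> QuantReport:
    """Full counting pipeline: extract, size, filter both masks, match, count."""
    gt_mask = np.asarray(gt_mask)
    pred_mask = np.asarray(pred_mask)
    if gt_mask.shape != pred_mask.shape:
        raise ValueError(
            f"shape mismatch: gt {gt_mask.shape} vs pred {pred_mask.shape}"
        )
    gt_kept = recruitable_filter(
        extract_follicles(gt_mask, pixel_spacing_mm), low, high)
    pred_kept = recruitable_filter(
        extract_follicles(pred_mask, pixel_spacing_mm), low, high)
    matches = match_follicles(gt_kept, pred_kept)
    n_real = len(gt_kept)
    n_detected = len(pred_kept)
    n_correct = len(matches)
    precision, recall = counting_rates(n_correct, n_detected, n_real)
    return QuantReport(
        n_real=n_real,
        n_detected=n_detected,
        n_correct=n_correct,
        precision=precision,
        recall=recall,
        matches=matches,
        degenerate=(n_detected == 0 or n_real == 0),
    )
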