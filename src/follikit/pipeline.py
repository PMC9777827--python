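"""The three-stage quantification pipeline: ovary segmentation, follicle
segmentation, follicle counting.

Stage chaining: the predicted follicle mask is intersected with the predicted
ovary mask before quantification (configurable), suppressing extra-ovarian
false positives.
"""

from __future__ import annotations

import numpy as np

from .network import HarmonicAttentionUNet, predict_mask
from .quantify import QuantReport, counting_report


def run_pipeline(image: np.ndarray,
                 ovary_model: HarmonicAttentionUNet,
                 follicle_model: HarmonicAttentionUNet,
                 pixel_spacing_mm: float,
                 gt_follicle_mask: np.ndarray | None = None,
                 input_size: int | None = None,
                 restrict_to_ovary: bool = True,
                 threshold: float = 0.5,
                 ) -> tuple[np.ndarray, np.ndarray, QuantReport | None]:
    """Run ovary -> follicle segmentation -> counting on one grayscale image.

    Returns (ovary mask, follicle mask, report).  The report is computed
    against ``gt_follicle_mask`` when provided, else None.
    """
    ovary_mask, _ = predict_mask(ovary_model, image, input_size=input_size,
                                 threshold=threshold)
    follicle_mask, _ = predict_mask(follicle_model, image, input_size=input_size,
                                    threshold=threshold)
    if restrict_to_ovary:
        follicle_mask = (follicle_mask & ovary_mask).astype(np.uint8)
    report = None
    if gt_follicle_mask is not None:
        report = counting_report(gt_follicle_mask, follicle_mask,
                                 pixel_spacing_mm)
    return ovary_mask, follicle_mask, report
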