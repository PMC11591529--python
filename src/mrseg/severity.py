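"""Regurgitant-fraction computation and mitral-regurgitation severity grading.

The severity index is the area-based regurgitant fraction

    RF = 100 * area(MR jet) / area(left atrium)

computed from a 3-class segmentation mask (0=background, 1=MR, 2=LA).
Because the jet occludes atrial pixels in a single-label mask, the atrial
area defaults to the union of jet and LA labels; ``la_includes_jet=False``
switches to the strict label-2 denominator. Being a ratio of pixel counts,
RF is invariant to image scale, which is the reason an area fraction rather
than an absolute area is used across devices with different image geometry.

Grading follows the guideline thresholds: RF < 30 mild, 30 <= RF < 50
moderate, RF >= 50 severe.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["SeverityResult", "regurgitant_fraction", "grade", "assess", "GRADES"]

GRADES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class SeverityResult:
    rf_percent: float
    grade: str
    mr_pixels: int
    la_pixels: int

    def as_dict(self) -> dict:
        return asdict(self)


def regurgitant_fraction(mask: np.ndarray, la_includes_jet: bool = True) -> SeverityResult:
    """RF percentage and grade from a label mask.

    Raises ``ValueError("no left atrium detected")`` when the denominator is
    empty — an all-background prediction must surface as an error, never as a
    silent grade.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    mr = int((mask == 1).sum())
    la = int((mask == 2).sum())
    denom = mr + la if la_includes_jet else la
    if denom == 0:
        raise ValueError("no left atrium detected")
    rf = 100.0 * mr / denom
    return SeverityResult(rf, grade(rf), mr, la)


def grade(rf_percent: float) -> str:
    """Guideline step function: <30 mild, [30, 50) moderate, >=50 severe."""
    if rf_percent < 0:
        raise ValueError("regurgitant fraction cannot be negative")
    if rf_percent < 30:
        return "mild"
    if rf_percent < 50:
        return "moderate"
    return "severe"


def assess(image: np.ndarray, model, la_includes_jet: bool = True) -> SeverityResult:
    """Segment ``image`` (H x W x 3 uint8) with ``model`` and grade the result."""
    from .models import predict

    pred = predict(model, image)
    return regurgitant_fraction(pred.mask, la_includes_jet=la_includes_jet)
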