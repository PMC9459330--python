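"""Percent-area plaque quantification from 8-bit histology images.

Replicates the fixed-threshold procedure: convert to 8-bit, apply one global
threshold chosen once and maintained for all images, and report the
percentage of ROI pixels above it.  No automatic (e.g. Otsu) thresholding is
performed by default — the threshold is a required input, because the
procedure's validity rests on it being held constant across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AreaFractionResult", "to_8bit", "area_fraction"]


@dataclass
class AreaFractionResult:
    area_pct: float  # 100 × suprathreshold ROI pixels / ROI pixels
    threshold: int
    n_roi_px: int
    n_suprathreshold_px: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_pct <= 100.0:
            raise ValueError("area_pct outside [0, 100]")


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linearly rescale an image's full value range onto 0–255 (uint8).

    Already-8-bit input is returned unchanged (as a copy); a constant image
    maps to constant 0.
    """
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.copy()
    img = image.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def area_fraction(
    image_8bit: np.ndarray,
    roi_mask: np.ndarray,
    threshold: int,
    comparator: str = "gt",
) -> AreaFractionResult:
    """Exact pixel-count fraction of ROI pixels above ``threshold``, ×100.

    ``comparator`` selects whether "suprathreshold" means strictly greater
    than (``"gt"``, default) or greater-or-equal (``"ge"``).  Pixels outside
    the mask never contribute.
    """
    image_8bit = np.asarray(image_8bit)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image_8bit.shape != roi_mask.shape:
        raise ValueError("image and ROI mask must have the same shape")
    if image_8bit.dtype != np.uint8:
        raise ValueError("image must be 8-bit; call to_8bit first")
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("ROI mask is empty")
    roi = image_8bit[roi_mask]
    if comparator == "gt":
        n_sup = int(np.count_nonzero(roi > threshold))
    elif comparator == "ge":
        n_sup = int(np.count_nonzero(roi >= threshold))
    else:
        raise ValueError("comparator must be 'gt' or 'ge'")
    return AreaFractionResult(
        area_pct=100.0 * n_sup / n_roi,
        threshold=int(threshold),
        n_roi_px=n_roi,
        n_suprathreshold_px=n_sup,
    )
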