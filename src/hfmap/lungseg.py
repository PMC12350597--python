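"""Lung-field segmentation of a CT slice.

A classical threshold-and-morphology recipe: binarize at an air-like HU
threshold, drop components touching the image border (ambient air), keep the
largest remaining components (the two lungs), close and hole-fill. Fully
parameterized; users with their own masks can bypass this module entirely.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

from .core import CTSlice, as_mask

__all__ = ["SegParams", "extract_lung_mask", "apply_mask"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegParams:
    """Segmentation knobs.

    air_threshold : HU below which tissue is considered air-like (default -320,
    between aerated lung ~ -850 and soft tissue ~ +40).
    keep_components : number of largest candidate components kept (default 2,
    one per lung; lungs that touch each other merge into one and still pass).
    closing_radius : disk radius (px) of the morphological closing that smooths
    the pleural boundary (default 5).
    fill_holes : fill enclosed holes (vessels, nodules) inside the mask.
    """

    air_threshold: float = -320.0
    keep_components: int = 2
    closing_radius: int = 5
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.air_threshold >= 0:
            raise ValueError("air_threshold must be negative (air-like HU)")
        if self.keep_components < 1:
            raise ValueError("keep_components must be >= 1")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")


def extract_lung_mask(ct: CTSlice, params: SegParams = SegParams()) -> np.ndarray:
    """Boolean lung-field mask of a CT slice.

    Returns an all-false mask (with a logged warning) when no candidate lung
    component survives, e.g. on a slice without aerated lung.
    """
    air = ct.hu < params.air_threshold
    air = segmentation.clear_border(air)
    labels, n = ndimage.label(air)
    if n == 0:
        logger.warning("no lung candidate found in slice %r: empty mask", ct.slice_id)
        return np.zeros(ct.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][: params.keep_components] + 1
    mask = np.isin(labels, keep)
    if params.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def apply_mask(ct: CTSlice, mask: np.ndarray, fill: float = 100.0) -> CTSlice:
    """Extract the lung-field image: HU outside the mask replaced by ``fill``.

    The fill value is cosmetic (for exported images); the HF-map stage masks
    pixels explicitly and never relies on the fill.
    """
    mask = as_mask(mask, ct.shape)
    hu = np.where(mask, ct.hu, fill)
    return CTSlice(hu, ct.spacing, ct.patient_id, ct.slice_id, ct.label)
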