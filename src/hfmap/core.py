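"""Core in-memory containers shared across the pipeline.

The unit of analysis is a single axial CT slice in Hounsfield units (HU),
together with a boolean lung-field mask on the same pixel grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised slice labels. ``fibrosis`` is the positive class everywhere.
LABELS = ("fibrosis", "non_fibrosis", "lung_cancer", "unknown")


@dataclass
class CTSlice:
    """A 2D Hounsfield-unit raster with its physical spacing and identity.

    Parameters
    ----------
    hu : ndarray, shape (rows, cols)
        Calibrated attenuation in HU (air ~ -1000, water = 0).
    spacing : (float, float)
        Pixel spacing in mm, (row pitch, column pitch); both > 0.
    patient_id, slice_id : str
        Identifiers used for patient-wise splitting and provenance.
    label : str
        One of :data:`LABELS`.
    """

    hu: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    patient_id: str = ""
    slice_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        if self.hu.ndim != 2 or self.hu.size == 0:
            raise ValueError("CTSlice.hu must be a non-empty 2D raster")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("CTSlice.hu must be finite")
        dr, dc = float(self.spacing[0]), float(self.spacing[1])
        if dr <= 0 or dc <= 0:
            raise ValueError("pixel spacing must be positive")
        self.spacing = (dr, dc)
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape


def as_mask(pixels: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and coerce a lung mask to a boolean raster."""
    m = np.asarray(pixels)
    if m.dtype != bool:
        uniq = np.unique(m)
        if not np.all(np.isin(uniq, (0, 1))) and not np.all(np.isin(uniq, (0, 255))):
            raise ValueError("mask must be two-valued")
        m = m > 0
    if m.ndim != 2 or m.size == 0:
        raise ValueError("mask must be a non-empty 2D raster")
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match slice shape {tuple(shape)}")
    return m


@dataclass
class FeatureRecord:
    """One slice-level observation for the classification stage."""

    patient_id: str
    slice_id: str
    feature: float
    label: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.feature):
            raise ValueError("feature must be finite")
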