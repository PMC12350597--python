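"""Synthetic CT-like slice phantoms with ground-truth lung masks.

The phantom emulates the HU structure the tile-shifted homology method reacts
to: an axial thorax (soft-tissue body ellipse over air background), two
aerated lungs with Gaussian HU noise and bright vessel cross-sections, and an
optional lesion —

* ``fibrosis``: a subpleural band tiled with a jittered honeycomb. Lumina sit
  at air-like HU; each wall segment (the shared wall between two neighbouring
  cells) gets one HU draw from Normal(wall_mean_hu + overlap_delta,
  wall_sd_hu). Inside the -700..-400 HU sweep only a subset of wall segments
  is therefore above threshold at any t, so the binarized tile fragments into
  many components — high b0, the discriminative signal.
* ``nodule``: a single soft-tissue disk (one extra component, low b0).

``overlap_delta`` shifts the wall HU distribution out of the sweep band and
is the single dial for degrading class separability in experiments.

Ground truth: the lung mask is exactly the union of the two analytic lung
ellipses, enabling exact Dice scoring of the segmentation stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import CTSlice

__all__ = [
    "FibrosisParams",
    "NoduleParams",
    "PhantomSpec",
    "CohortSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class FibrosisParams:
    """Subpleural honeycomb-band geometry and wall HU distribution."""

    band_width_mm: float = 12.0
    cell_diameter_mm: float = 4.0
    wall_mean_hu: float = -550.0
    wall_sd_hu: float = 100.0
    lumen_hu: float = -820.0


@dataclass(frozen=True)
class NoduleParams:
    radius_mm: float = 12.0
    hu: float = 20.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice; ``seed`` determines the output."""

    image_size: int = 256
    spacing: float = 0.7
    body_hu: float = 40.0
    lung_hu: float = -850.0
    noise_sd: float = 30.0
    n_vessels: int = 15
    vessel_hu: float = 0.0
    lesion: str = "none"
    fibrosis: FibrosisParams = field(default_factory=FibrosisParams)
    nodule: NoduleParams = field(default_factory=NoduleParams)
    overlap_delta: float = 0.0
    seed: int | tuple[int, ...] = 0

    def __post_init__(self) -> None:
        if self.lesion not in ("none", "fibrosis", "nodule"):
            raise ValueError("lesion must be 'none', 'fibrosis' or 'nodule'")
        for v in (self.body_hu, self.lung_hu, self.vessel_hu, self.fibrosis.wall_mean_hu,
                  self.fibrosis.lumen_hu, self.nodule.hu):
            if not -1024 <= v <= 1024:
                raise ValueError("HU parameters must lie in [-1024, 1024]")


@dataclass
class PhantomSample:
    ct: CTSlice
    mask: np.ndarray  # analytic ground-truth lung mask
    label: str


_LESION_LABEL = {"none": "non_fibrosis", "fibrosis": "fibrosis", "nodule": "lung_cancer"}


def _ellipse(shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _lung_geometry(n: int):
    centers = [(0.52 * n, 0.30 * n), (0.52 * n, 0.70 * n)]
    semi = (0.28 * n, 0.15 * n)
    return centers, semi


def _honeycomb_band(hu, band, spacing, fp: FibrosisParams, delta, rng) -> None:
    """Overwrite the band pixels with lumina and per-segment wall HU in place."""
    n = hu.shape[0]
    pitch = fp.cell_diameter_mm / spacing  # px between cell centers
    row_pitch = pitch * np.sqrt(3.0) / 2.0
    rows = np.arange(0, n + pitch, row_pitch)
    cols = np.arange(0, n + pitch, pitch)
    centers = []
    for i, r in enumerate(rows):
        off = 0.5 * pitch if i % 2 else 0.0
        for c in cols:
            centers.append((r, c + off))
    centers = np.asarray(centers)
    centers = centers + rng.uniform(-0.15 * pitch, 0.15 * pitch, size=centers.shape)

    pts = np.argwhere(band)
    tree = cKDTree(centers)
    dist, idx = tree.query(pts, k=2)
    lumen = dist[:, 0] <= 0.30 * pitch
    # one HU draw per wall segment = per unordered pair of adjacent cells
    pairs = np.sort(idx, axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    seg_hu = rng.normal(fp.wall_mean_hu + delta, fp.wall_sd_hu, size=uniq.shape[0])
    vals = np.where(lumen, fp.lumen_hu, seg_hu[inverse])
    hu[pts[:, 0], pts[:, 1]] = vals


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one slice. Raises if the requested lesion does not fit the lung."""
    n = spec.image_size
    rng = np.random.default_rng(spec.seed if isinstance(spec.seed, int) else list(spec.seed))
    hu = np.full((n, n), -1000.0)
    body = _ellipse((n, n), (0.50 * n, 0.50 * n), (0.44 * n, 0.47 * n))
    hu[body] = spec.body_hu
    centers, semi = _lung_geometry(n)
    lungs = _ellipse((n, n), centers[0], semi) | _ellipse((n, n), centers[1], semi)
    hu[lungs] = spec.lung_hu + rng.normal(0.0, spec.noise_sd, size=int(lungs.sum()))

    if spec.lesion == "fibrosis":
        band_px = spec.fibrosis.band_width_mm / spec.spacing
        dist_in = ndimage.distance_transform_edt(lungs)
        band = lungs & (dist_in <= band_px)
        if not band.any():
            raise ValueError("fibrosis band does not fit inside the lung")
        _honeycomb_band(hu, band, spec.spacing, spec.fibrosis, spec.overlap_delta, rng)

    # vessel cross-sections: small soft-tissue disks inside the lungs
    for _ in range(spec.n_vessels):
        radius = rng.uniform(0.7, 1.8) / spec.spacing
        side = int(rng.integers(0, 2))
        cr, cc = centers[side]
        r = cr + rng.uniform(-0.8, 0.8) * semi[0]
        c = cc + rng.uniform(-0.8, 0.8) * semi[1]
        disk = _ellipse((n, n), (r, c), (radius, radius)) & lungs
        hu[disk] = spec.vessel_hu

    if spec.lesion == "nodule":
        radius = spec.nodule.radius_mm / spec.spacing
        cr, cc = centers[1]
        disk = _ellipse((n, n), (cr, cc), (radius, radius))
        if not (disk <= lungs).all():
            raise ValueError("nodule does not fit inside the lung")
        hu[disk] = spec.nodule.hu

    np.clip(hu, -1024.0, 1024.0, out=hu)
    ct = CTSlice(hu, (spec.spacing, spec.spacing), label=_LESION_LABEL[spec.lesion])
    return PhantomSample(ct, lungs, ct.label)


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of phantom patients, several per class, a few slices each.

    ``n_patients`` maps a lesion kind ("none" | "fibrosis" | "nodule") to a
    patient count; per-slice seeds derive deterministically from ``base_seed``
    so two cohorts from the same spec are identical.
    """

    n_patients: dict = field(default_factory=lambda: {"fibrosis": 10, "none": 10})
    slices_per_patient: int = 2
    template: PhantomSpec = field(default_factory=PhantomSpec)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.slices_per_patient < 1:
            raise ValueError("slices_per_patient must be >= 1")
        for k in self.n_patients:
            if k not in ("none", "fibrosis", "nodule"):
                raise ValueError(f"unknown lesion class {k!r}")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[PhantomSample]]:
    """Generate all slices of a cohort plus its manifest.

    The manifest records (patient_id, slice_id, label); samples are returned
    in manifest order. Writing to disk is handled by :mod:`hfmap.io`.
    """
    rows = []
    samples = []
    for ci, (lesion, n_pat) in enumerate(sorted(spec.n_patients.items())):
        for pi in range(n_pat):
            pid = f"{_LESION_LABEL[lesion]}_{pi:02d}"
            for si in range(spec.slices_per_patient):
                sub = replace(spec.template, lesion=lesion, seed=(spec.base_seed, ci, pi, si))
                sample = generate_phantom(sub)
                sid = f"{pid}_s{si}"
                sample.ct.patient_id = pid
                sample.ct.slice_id = sid
                rows.append({"patient_id": pid, "slice_id": sid, "label": sample.label})
                samples.append(sample)
    return pd.DataFrame(rows), samples
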