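"""Tile-shifted HF (homology-feature) maps.

A tile (default 32x32 px) slides across the slice on a fixed stride (default
8 px). Each tile wholly inside the raster and sufficiently covered by the
lung mask yields a homology profile; the profile's scalar summary is
standardized (by pixel area, by default) and ADDED to every pixel of the tile
footprint. Overlapping contributions sum — no coverage normalisation. The
slice-level feature is the maximum of the resulting map.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import CTSlice, as_mask
from .hp_profile import ProfileParams

__all__ = [
    "MapParams",
    "StandardizationSpec",
    "HFMap",
    "iter_tiles",
    "tile_skip",
    "standardize",
    "compute_hf_map",
    "compute_hf_map_pair",
    "slice_feature",
]

logger = logging.getLogger(__name__)

STANDARDIZATIONS = ("pixel_area", "pixel_spacing", "tile_pixels", "none")


@dataclass(frozen=True)
class MapParams:
    """Configuration of the tile-shifted map.

    tile_size
        Tile edge in pixels (default 32).
    shift
        Stride between tile origins in pixels (default 8); 1 <= shift <= tile_size.
    skip_fraction
        A tile is skipped when strictly more than this fraction of its pixels
        lies OUTSIDE the lung mask (default 0.95; a fraction of exactly 0.95
        is kept).
    standardization
        How the per-tile summary is scaled before accumulation:
        "pixel_area" (divide by row-pitch * col-pitch in mm^2, the default),
        "pixel_spacing" (divide by the row pitch; isotropic assumption),
        "tile_pixels" (divide by the tile's in-mask pixel count), or "none".
    profile, index, mode
        Sweep parameters and which profile summary feeds the map
        (default: max of b0).
    """

    tile_size: int = 32
    shift: int = 8
    skip_fraction: float = 0.95
    standardization: str = "pixel_area"
    profile: ProfileParams = field(default_factory=ProfileParams)
    index: str = "b0"
    mode: str = "max"

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if not 1 <= self.shift <= self.tile_size:
            raise ValueError("shift must satisfy 1 <= shift <= tile_size")
        if not 0 < self.skip_fraction <= 1:
            raise ValueError("skip_fraction must lie in (0, 1]")
        if self.standardization not in STANDARDIZATIONS:
            raise ValueError(f"standardization must be one of {STANDARDIZATIONS}")
        if self.index not in ("b0", "b1"):
            raise ValueError("index must be 'b0' or 'b1'")
        if self.mode not in ("max", "argmax"):
            raise ValueError("mode must be 'max' or 'argmax'")


@dataclass(frozen=True)
class StandardizationSpec:
    mode: str
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in STANDARDIZATIONS:
            raise ValueError(f"mode must be one of {STANDARDIZATIONS}")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass
class HFMap:
    """Accumulated standardized tile summaries on the slice pixel grid."""

    values: np.ndarray
    params: MapParams
    provenance: str = ""
    spacing: tuple[float, float] = (1.0, 1.0)
    n_tiles: int = 0
    n_skipped: int = 0


def iter_tiles(shape: tuple[int, int], tile_size: int, shift: int) -> list[tuple[int, int]]:
    """Row-major origins of all tiles lying fully inside ``shape``.

    Origins run over {0, shift, 2*shift, ...} on each axis; no padding, so a
    tile never crosses the raster edge.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if tile_size > rows or tile_size > cols:
        raise ValueError(f"tile_size {tile_size} exceeds raster shape {(rows, cols)}")
    r_orig = range(0, rows - tile_size + 1, shift)
    c_orig = range(0, cols - tile_size + 1, shift)
    return [(r, c) for r in r_orig for c in c_orig]


def tile_skip(tile_mask: np.ndarray, skip_fraction: float = 0.95) -> bool:
    """True when the tile must be skipped.

    The rule is strict: skip only when the fraction of tile pixels outside the
    lung mask exceeds ``skip_fraction``; a fraction exactly equal is kept.
    """
    m = np.asarray(tile_mask, dtype=bool)
    outside = 1.0 - np.count_nonzero(m) / m.size
    return outside > skip_fraction


def standardize(raw: float, spec: StandardizationSpec, tile_valid_pixels: int = 0) -> float:
    """Scale a per-tile summary so maps are comparable across pixel sizes."""
    if spec.mode == "pixel_area":
        return raw / (spec.pixel_spacing[0] * spec.pixel_spacing[1])
    if spec.mode == "pixel_spacing":
        return raw / spec.pixel_spacing[0]
    if spec.mode == "tile_pixels":
        if tile_valid_pixels <= 0:
            raise ValueError("tile_pixels standardization requires valid pixels in the tile")
        return raw / tile_valid_pixels
    return float(raw)


def _accumulate(
    ct: CTSlice, mask: np.ndarray, params: MapParams
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """One pass over all tiles, accumulating both the b0 and b1 maps."""
    hu = np.ascontiguousarray(ct.hu, dtype=np.float64)
    mask = np.ascontiguousarray(mask, dtype=bool)
    ts = params.profile.thresholds()
    spec = StandardizationSpec(params.standardization, ct.spacing)
    out_b0 = np.zeros(hu.shape, dtype=np.float64)
    out_b1 = np.zeros(hu.shape, dtype=np.float64)
    origins = iter_tiles(hu.shape, params.tile_size, params.shift)
    n_skipped = 0
    k = params.tile_size
    for r, c in origins:
        tm = mask[r : r + k, c : c + k]
        if tile_skip(tm, params.skip_fraction):
            n_skipped += 1
            continue
        valid = int(np.count_nonzero(tm))
        if valid == 0:
            # only reachable with skip_fraction == 1.0; an empty tile has an
            # empty profile and contributes nothing
            continue
        b0, b1 = _kernels.betti_profile(
            hu[r : r + k, c : c + k],
            tm,
            ts,
            params.profile.connectivity.foreground,
            params.profile.connectivity.background,
            params.profile.polarity == "ge",
        )
        if params.mode == "max":
            raw0, raw1 = float(b0.max()), float(b1.max())
        else:
            raw0 = float(ts[int(np.argmax(b0))])
            raw1 = float(ts[int(np.argmax(b1))])
        out_b0[r : r + k, c : c + k] += standardize(raw0, spec, valid)
        out_b1[r : r + k, c : c + k] += standardize(raw1, spec, valid)
    return out_b0, out_b1, len(origins), n_skipped


def compute_hf_map_pair(ct: CTSlice, mask: np.ndarray, params: MapParams = MapParams()) -> tuple[HFMap, HFMap]:
    """Compute the b0 and b1 HF maps in a single pass over the tiles.

    Both Betti sequences fall out of the same filtration, so asking for both
    costs essentially one map computation.
    """
    mask = as_mask(mask, ct.shape)
    if not mask.any():
        logger.warning("empty lung mask for slice %r: HF map is all zero", ct.slice_id)
        zero = np.zeros(ct.shape, dtype=np.float64)
        n = len(iter_tiles(ct.shape, params.tile_size, params.shift))
        return (
            HFMap(zero.copy(), params, ct.slice_id, ct.spacing, n, n),
            HFMap(zero.copy(), params, ct.slice_id, ct.spacing, n, n),
        )
    m0, m1, n_tiles, n_skipped = _accumulate(ct, mask, params)
    return (
        HFMap(m0, params, ct.slice_id, ct.spacing, n_tiles, n_skipped),
        HFMap(m1, params, ct.slice_id, ct.spacing, n_tiles, n_skipped),
    )


def compute_hf_map(ct: CTSlice, mask: np.ndarray, params: MapParams = MapParams()) -> HFMap:
    """Tile-shifted HF map for the index selected in ``params`` (default b0)."""
    pair = compute_hf_map_pair(ct, mask, params)
    return pair[0] if params.index == "b0" else pair[1]


def slice_feature(hf_map: HFMap) -> float:
    """The slice-level feature: the maximum pixel of the HF map."""
    return float(hf_map.values.max())
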