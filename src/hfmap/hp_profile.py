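"""Homology profiles: Betti numbers of a tile across an HU threshold sweep.

A tile of HU values is binarized at every threshold of a sweep (default
-700..-400 HU, 1 HU step — the attenuation band reported for fibrotic lung
tissue) and the (b0, b1) pair is recorded at each threshold. The scalar
summary of a profile (its maximum, or the threshold attaining it) is the
per-tile quantity accumulated into the HF map.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .topology import ConnectivityRule, DEFAULT_CONNECTIVITY, BettiPair, betti_numbers

__all__ = [
    "ProfileParams",
    "HomologyProfile",
    "ProfileSummary",
    "binarize",
    "homology_profile",
    "summarize_profile",
]


@dataclass(frozen=True)
class ProfileParams:
    """Sweep configuration for the homology profile.

    Parameters
    ----------
    threshold_lo, threshold_hi : float
        Sweep bounds in HU, inclusive. Default -700..-400 HU.
    threshold_step : float
        Sweep step in HU (> 0). 1 HU is the finest meaningful step for
        integer-valued HU data. If the step does not divide the range the
        final threshold is clipped to ``threshold_hi``.
    polarity : {"ge", "le"}
        "ge": foreground = pixels with HU >= t (dense tissue is foreground,
        the default — fibrous structure is denser than aerated lung);
        "le": foreground = HU <= t.
    connectivity : ConnectivityRule
        Foreground/background adjacency pairing.
    """

    threshold_lo: float = -700.0
    threshold_hi: float = -400.0
    threshold_step: float = 1.0
    polarity: str = "ge"
    connectivity: ConnectivityRule = field(default_factory=ConnectivityRule)

    def __post_init__(self) -> None:
        if self.threshold_lo > self.threshold_hi:
            raise ValueError("threshold_lo must not exceed threshold_hi")
        if self.threshold_step <= 0:
            raise ValueError("threshold_step must be positive")
        if self.polarity not in ("ge", "le"):
            raise ValueError("polarity must be 'ge' or 'le'")

    def thresholds(self) -> np.ndarray:
        """Ascending sweep thresholds, clipped so the last equals threshold_hi."""
        n = int(np.floor((self.threshold_hi - self.threshold_lo) / self.threshold_step + 1e-9)) + 1
        ts = self.threshold_lo + self.threshold_step * np.arange(n, dtype=np.float64)
        if ts[-1] < self.threshold_hi - 1e-9:
            ts = np.append(ts, self.threshold_hi)
        return ts


@dataclass
class HomologyProfile:
    """Per-tile (threshold, b0, b1) sequence over the sweep.

    ``empty`` marks the distinct signal for a tile with no valid (in-mask)
    pixel; it carries zero-length Betti arrays and cannot be summarized.
    """

    thresholds: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    empty: bool = False

    @property
    def entries(self) -> list[tuple[float, BettiPair]]:
        return [
            (float(t), BettiPair(int(a), int(b)))
            for t, a, b in zip(self.thresholds, self.b0, self.b1)
        ]

    def sequence(self, index: str) -> np.ndarray:
        if index not in ("b0", "b1"):
            raise ValueError("index must be 'b0' or 'b1'")
        return self.b0 if index == "b0" else self.b1


@dataclass(frozen=True)
class ProfileSummary:
    """Scalar summary of a profile: a count (mode="max") or an HU (mode="argmax")."""

    index: str
    mode: str
    value: float


def binarize(
    tile_hu: np.ndarray,
    tile_mask: np.ndarray,
    t: float,
    params: ProfileParams = ProfileParams(),
) -> np.ndarray:
    """Threshold a tile: foreground where the polarity predicate holds in-mask.

    Pixels outside ``tile_mask`` are background at every threshold; they never
    create components nor close holes.
    """
    hu = np.asarray(tile_hu, dtype=np.float64)
    mask = np.asarray(tile_mask, dtype=bool)
    if hu.shape != mask.shape:
        raise ValueError(f"tile shape {hu.shape} != mask shape {mask.shape}")
    pred = hu >= t if params.polarity == "ge" else hu <= t
    return pred & mask


def homology_profile(
    tile_hu: np.ndarray,
    tile_mask: np.ndarray,
    params: ProfileParams = ProfileParams(),
    engine: str = "fast",
) -> HomologyProfile:
    """Betti numbers of the binarized tile at every sweep threshold.

    ``engine="fast"`` runs the incremental union-find filtration (one pass for
    the whole sweep); ``engine="reference"`` relabels the tile independently
    at each threshold via :func:`hfmap.topology.betti_numbers`. The two are
    exactly equivalent; the reference path exists as a cross-check and for
    exotic configurations.
    """
    hu = np.asarray(tile_hu, dtype=np.float64)
    mask = np.asarray(tile_mask, dtype=bool)
    if hu.shape != mask.shape:
        raise ValueError(f"tile shape {hu.shape} != mask shape {mask.shape}")
    ts = params.thresholds()
    if not mask.any():
        return HomologyProfile(ts, np.zeros(0, np.int64), np.zeros(0, np.int64), empty=True)
    if engine == "fast":
        b0, b1 = _kernels.betti_profile(
            hu,
            mask,
            ts,
            params.connectivity.foreground,
            params.connectivity.background,
            params.polarity == "ge",
        )
    elif engine == "reference":
        b0 = np.empty(ts.size, np.int64)
        b1 = np.empty(ts.size, np.int64)
        for i, t in enumerate(ts):
            pair = betti_numbers(binarize(hu, mask, t, params), params.connectivity)
            b0[i], b1[i] = pair.b0, pair.b1
    else:
        raise ValueError("engine must be 'fast' or 'reference'")
    return HomologyProfile(ts, b0, b1)


def summarize_profile(
    profile: HomologyProfile, index: str = "b0", mode: str = "max"
) -> ProfileSummary:
    """Collapse a profile to its scalar summary.

    mode="max": maximum of the chosen Betti sequence (a count).
    mode="argmax": the lowest threshold attaining that maximum (an HU value);
    ties break toward the lowest threshold, deterministically.
    """
    if profile.empty or profile.thresholds.size == 0:
        raise ValueError("cannot summarize an empty profile")
    if mode not in ("max", "argmax"):
        raise ValueError("mode must be 'max' or 'argmax'")
    seq = profile.sequence(index)
    if mode == "max":
        return ProfileSummary(index, mode, float(seq.max()))
    return ProfileSummary(index, mode, float(profile.thresholds[int(np.argmax(seq))]))
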