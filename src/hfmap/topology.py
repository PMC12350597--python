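"""2D cubical Betti numbers of binary images.

b0 counts connected foreground components; b1 counts holes, i.e. background
components that do not reach the raster border. Foreground and background use
dual adjacencies (8/4 by default) so that component and hole counts are
consistent (no Jordan-curve paradoxes) and the bit-quad Euler characteristic
satisfies chi = b0 - b1.

Three routes are provided on purpose:

* :func:`betti_numbers` — the production path (scipy component labeling);
* :func:`flood_fill_oracle` — a structurally independent stack-based flood
  fill with the same contract, used to cross-check the production path;
* :func:`euler_characteristic` — Gray's bit-quad counting, a second
  independent consistency oracle via the identity chi = b0 - b1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ConnectivityRule",
    "BettiPair",
    "betti_numbers",
    "flood_fill_oracle",
    "euler_characteristic",
]

_OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


@dataclass(frozen=True)
class ConnectivityRule:
    """Adjacency convention for the two phases of a binary image.

    Foreground and background adjacencies must differ (digital-topology
    duality). Default: 8-adjacent foreground, 4-adjacent background.
    """

    foreground: int = 8
    background: int = 4

    def __post_init__(self) -> None:
        if self.foreground not in (4, 8) or self.background not in (4, 8):
            raise ValueError("adjacency must be 4 or 8")
        if self.foreground == self.background:
            raise ValueError("foreground and background adjacency must differ")


DEFAULT_CONNECTIVITY = ConnectivityRule()


@dataclass(frozen=True)
class BettiPair:
    """(b0, b1): number of foreground components and number of holes."""

    b0: int
    b1: int

    def __post_init__(self) -> None:
        if self.b0 < 0 or self.b1 < 0:
            raise ValueError("Betti numbers are non-negative")
        if self.b0 == 0 and self.b1 != 0:
            raise ValueError("an image with no foreground has no holes")


def _validate(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("binary image must be a non-empty 2D raster")
    if a.dtype != bool:
        vals = np.unique(a)
        if vals.size > 2 or not np.all(np.isin(vals, (0, 1))):
            raise ValueError("image must be strictly two-valued")
        a = a.astype(bool)
    return a


def _structure(adjacency: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if adjacency == 4 else 2)


def betti_numbers(img: np.ndarray, conn: ConnectivityRule = DEFAULT_CONNECTIVITY) -> BettiPair:
    """Compute (b0, b1) of a binary image.

    b0 is the number of foreground components under ``conn.foreground``; b1 is
    the number of background components under ``conn.background`` that contain
    no border pixel.
    """
    a = _validate(img)
    _, b0 = ndimage.label(a, structure=_structure(conn.foreground))
    bg_labels, n_bg = ndimage.label(~a, structure=_structure(conn.background))
    if n_bg == 0:
        return BettiPair(int(b0), 0)
    border = np.concatenate(
        [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
    )
    touching = np.unique(border[border > 0])
    return BettiPair(int(b0), int(n_bg - touching.size))


def flood_fill_oracle(img: np.ndarray, conn: ConnectivityRule = DEFAULT_CONNECTIVITY) -> BettiPair:
    """Same contract as :func:`betti_numbers` via explicit stack flood fill.

    Deliberately avoids scipy labeling so it can serve as an independent
    oracle in tests.
    """
    a = _validate(img)
    rows, cols = a.shape

    def count_components(target: bool, offsets, exclude_border: bool) -> int:
        seen = np.zeros_like(a, dtype=bool)
        count = 0
        for r0 in range(rows):
            for c0 in range(cols):
                if a[r0, c0] != target or seen[r0, c0]:
                    continue
                stack = [(r0, c0)]
                seen[r0, c0] = True
                touches_border = False
                while stack:
                    r, c = stack.pop()
                    if r in (0, rows - 1) or c in (0, cols - 1):
                        touches_border = True
                    for dr, dc in offsets:
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < rows and 0 <= nc < cols:
                            if a[nr, nc] == target and not seen[nr, nc]:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                if not (exclude_border and touches_border):
                    count += 1
        return count

    b0 = count_components(True, _OFFSETS[conn.foreground], exclude_border=False)
    b1 = count_components(False, _OFFSETS[conn.background], exclude_border=True)
    return BettiPair(b0, b1)


def euler_characteristic(img: np.ndarray, conn: ConnectivityRule = DEFAULT_CONNECTIVITY) -> int:
    """Euler characteristic chi = b0 - b1 from local 2x2 bit-quad counts.

    Uses Gray's formulas: chi4 = (Q1 - Q3 + 2 Qd) / 4 for 4-adjacent
    foreground and chi8 = (Q1 - Q3 - 2 Qd) / 4 for 8-adjacent foreground,
    where Q1/Q3 count 2x2 windows with one/three foreground pixels and Qd the
    diagonal pairs. Entirely local, hence independent of any labeling.
    """
    a = _validate(img)
    p = np.pad(a, 1, constant_values=False)
    q00 = p[:-1, :-1]
    q01 = p[:-1, 1:]
    q10 = p[1:, :-1]
    q11 = p[1:, 1:]
    s = (
        q00.astype(np.int8) + q01.astype(np.int8) + q10.astype(np.int8) + q11.astype(np.int8)
    )
    n1 = int(np.count_nonzero(s == 1))
    n3 = int(np.count_nonzero(s == 3))
    diag = (s == 2) & ((q00 & q11) | (q01 & q10))
    nd = int(np.count_nonzero(diag))
    if conn.foreground == 4:
        chi4 = n1 - n3 + 2 * nd
        assert chi4 % 4 == 0
        return chi4 // 4
    chi8 = n1 - n3 - 2 * nd
    assert chi8 % 4 == 0
    return chi8 // 4
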