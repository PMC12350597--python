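"""Incremental union-find kernel for whole-sweep Betti profiles.

Computing a homology profile by relabeling the tile at every threshold costs
O(T * N) labelings. Because superlevel (or sublevel) sets are nested along the
sweep, both Betti sequences can instead be obtained in a single incremental
pass each: pixels are inserted in order of their HU value and merged with
already-present neighbours by union-find, so

    b0(t) = (#foreground pixels inserted) - (#effective merges)

and, with a virtual "outside" node that all border background pixels join,

    b1(t) = (#background pixels inserted) - (#effective merges)

(the outside-connected component is subtracted by construction). This is the
standard 0-dimensional filtration trick; the per-threshold relabeling path is
kept in :mod:`hfmap.hp_profile` as a reference engine and the two are asserted
equivalent in the test suite.

The kernel assumes foreground = (HU >= t). The <=-polarity case is handled by
the caller through value/threshold negation.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# neighbour offset tables, 4- and 8-adjacency
_DR8 = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_DC8 = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
_DR4 = np.array([-1, 1, 0, 0], dtype=np.int64)
_DC4 = np.array([0, 0, -1, 1], dtype=np.int64)


@njit(cache=True)
def _find(parent: np.ndarray, x: int) -> int:
    while parent[x] != x:
        parent[x] = parent[parent[x]]  # path halving
        x = parent[x]
    return x


@njit(cache=True)
def _profile_ge(hu, mask, thresholds, dr_fg, dc_fg, dr_bg, dc_bg):
    rows, cols = hu.shape
    n = rows * cols
    t_count = thresholds.shape[0]
    b0 = np.zeros(t_count, dtype=np.int64)
    b1 = np.zeros(t_count, dtype=np.int64)

    # values and flat indices of in-mask pixels, sorted ascending by HU
    m = 0
    for i in range(rows):
        for j in range(cols):
            if mask[i, j]:
                m += 1
    vals = np.empty(m, dtype=np.float64)
    pix = np.empty(m, dtype=np.int64)
    k = 0
    for i in range(rows):
        for j in range(cols):
            if mask[i, j]:
                vals[k] = hu[i, j]
                pix[k] = i * cols + j
                k += 1
    order = np.argsort(vals)

    # --- foreground pass: F(t) = {in-mask pixels with hu >= t}, shrinking in t
    parent = np.full(n, -1, dtype=np.int64)
    added = 0
    merges = 0
    p = m - 1
    for ti in range(t_count - 1, -1, -1):
        t = thresholds[ti]
        while p >= 0 and vals[order[p]] >= t:
            px = pix[order[p]]
            parent[px] = px
            added += 1
            r = px // cols
            c = px % cols
            for o in range(dr_fg.shape[0]):
                nr = r + dr_fg[o]
                nc = c + dc_fg[o]
                if 0 <= nr < rows and 0 <= nc < cols:
                    q = nr * cols + nc
                    if parent[q] >= 0:
                        ra = _find(parent, px)
                        rb = _find(parent, q)
                        if ra != rb:
                            parent[ra] = rb
                            merges += 1
            p -= 1
        b0[ti] = added - merges

    # --- background pass: B(t) = out-of-mask pixels + {in-mask, hu < t},
    # growing in t; virtual outside node absorbs border-touching components
    out_node = n
    parent2 = np.full(n + 1, -1, dtype=np.int64)
    parent2[out_node] = out_node
    added2 = 0
    merges2 = 0
    for i in range(rows):
        for j in range(cols):
            if not mask[i, j]:
                px = i * cols + j
                parent2[px] = px
                added2 += 1
                for o in range(dr_bg.shape[0]):
                    nr = i + dr_bg[o]
                    nc = j + dc_bg[o]
                    if 0 <= nr < rows and 0 <= nc < cols:
                        q = nr * cols + nc
                        if parent2[q] >= 0:
                            ra = _find(parent2, px)
                            rb = _find(parent2, q)
                            if ra != rb:
                                parent2[ra] = rb
                                merges2 += 1
                if i == 0 or i == rows - 1 or j == 0 or j == cols - 1:
                    ra = _find(parent2, px)
                    rb = _find(parent2, out_node)
                    if ra != rb:
                        parent2[ra] = rb
                        merges2 += 1
    p = 0
    for ti in range(t_count):
        t = thresholds[ti]
        while p < m and vals[order[p]] < t:
            px = pix[order[p]]
            parent2[px] = px
            added2 += 1
            r = px // cols
            c = px % cols
            for o in range(dr_bg.shape[0]):
                nr = r + dr_bg[o]
                nc = c + dc_bg[o]
                if 0 <= nr < rows and 0 <= nc < cols:
                    q = nr * cols + nc
                    if parent2[q] >= 0:
                        ra = _find(parent2, px)
                        rb = _find(parent2, q)
                        if ra != rb:
                            parent2[ra] = rb
                            merges2 += 1
            if r == 0 or r == rows - 1 or c == 0 or c == cols - 1:
                ra = _find(parent2, px)
                rb = _find(parent2, out_node)
                if ra != rb:
                    parent2[ra] = rb
                    merges2 += 1
            p += 1
        b1[ti] = added2 - merges2

    return b0, b1


def betti_profile(
    hu: np.ndarray,
    mask: np.ndarray,
    thresholds: np.ndarray,
    fg_adjacency: int,
    bg_adjacency: int,
    polarity_ge: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Betti sequences (b0[t], b1[t]) over an ascending threshold sweep.

    ``polarity_ge`` selects foreground = (HU >= t); otherwise (HU <= t), which
    reduces to the >= case under negation of values and thresholds.
    """
    hu = np.ascontiguousarray(hu, dtype=np.float64)
    mask = np.ascontiguousarray(mask, dtype=bool)
    thresholds = np.ascontiguousarray(thresholds, dtype=np.float64)
    dr_fg, dc_fg = (_DR8, _DC8) if fg_adjacency == 8 else (_DR4, _DC4)
    dr_bg, dc_bg = (_DR8, _DC8) if bg_adjacency == 8 else (_DR4, _DC4)
    if polarity_ge:
        return _profile_ge(hu, mask, thresholds, dr_fg, dc_fg, dr_bg, dc_bg)
    b0, b1 = _profile_ge(-hu, mask, -thresholds[::-1], dr_fg, dc_fg, dr_bg, dc_bg)
    return b0[::-1].copy(), b1[::-1].copy()
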