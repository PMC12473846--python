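"""Contour extraction from binary images.

Each 8-connected white component yields one outer contour, traced with
Moore-neighbor border following (clockwise, Jacob's stopping criterion).
Straight horizontal, vertical and diagonal runs of the traced boundary are
compressed to their endpoints, so an axis-aligned rectangle reduces to its
four corners while remaining losslessly re-expandable.  Components whose
boundary touches the frame edge are flagged: such objects are partially
outside the field of view and are rejected before the animal decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import BBox, GrayImage

_EIGHT = np.ones((3, 3), dtype=bool)
# clockwise Moore neighborhood in (row, col), row axis pointing down
_CW = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_CW_INDEX = {off: i for i, off in enumerate(_CW)}


@dataclass(frozen=True)
class Contour:
    """Compressed outer boundary of one white component."""

    points: tuple[tuple[int, int], ...]  # ordered (row, col) polyline, closed
    bbox: BBox  # half-open (r0, c0, r1, c1) of the component
    touches_border: bool
    area_px: int  # component pixel count

    def expand(self) -> list[tuple[int, int]]:
        """Re-expand the compressed polyline to the full traced boundary."""
        if len(self.points) == 1:
            return list(self.points)
        full: list[tuple[int, int]] = []
        pts = list(self.points) + [self.points[0]]
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            n = max(abs(r1 - r0), abs(c1 - c0))
            sr = (r1 - r0) // n if n else 0
            sc = (c1 - c0) // n if n else 0
            for i in range(n):
                full.append((r0 + i * sr, c0 + i * sc))
        return full


def _trace_boundary(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbor border following on a padded component mask."""
    sr, sc = start
    # entering backtrack: the west neighbor, background since `start` is the
    # leftmost pixel of the component's topmost row
    boundary = [start]
    cur = start
    back = (sr, sc - 1)
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    while True:
        dr, dc = back[0] - cur[0], back[1] - cur[1]
        k = _CW_INDEX[(dr, dc)]
        nxt = None
        prev = back
        for i in range(1, 9):
            off = _CW[(k + i) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if mask[cand]:
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated single pixel
            return boundary
        if first_move is None:
            first_move = (cur, nxt)
        elif cur == start and (cur, nxt) == first_move:
            return boundary[:-1] if boundary[-1] == start else boundary
        back = prev
        cur = nxt
        boundary.append(cur)


def _compress(boundary: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Drop interior points of straight 8-direction runs (circular)."""
    n = len(boundary)
    if n <= 2:
        return tuple(boundary)
    kept = []
    for i in range(n):
        p_prev = boundary[(i - 1) % n]
        p = boundary[i]
        p_next = boundary[(i + 1) % n]
        d_in = (p[0] - p_prev[0], p[1] - p_prev[1])
        d_out = (p_next[0] - p[0], p_next[1] - p[1])
        if d_in != d_out:
            kept.append(p)
    return tuple(kept) if kept else (boundary[0],)


def find_contours(img: GrayImage) -> list[Contour]:
    """Extract one outer contour per 8-connected white component.

    The input must be binary: exactly one nonzero level (any ``i_max``).
    Contours are returned in raster order of their topmost-leftmost pixel.
    """
    arr = np.asarray(img)
    values = np.unique(arr)
    nonzero = values[values != 0]
    if nonzero.size > 1:
        raise TypeError(
            f"expected a binary image with one nonzero level, found {nonzero.tolist()}"
        )
    h, w = arr.shape
    labels, n = ndimage.label(arr != 0, structure=_EIGHT)
    contours: list[Contour] = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(labels == idx)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        # pad by 1 so the tracer never leaves the submask
        sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
        sub[rows - r0 + 1, cols - c0 + 1] = True
        start_i = int(np.lexsort((cols, rows))[0])
        start = (int(rows[start_i]) - r0 + 1, int(cols[start_i]) - c0 + 1)
        traced = _trace_boundary(sub, start)
        pts = tuple((r + r0 - 1, c + c0 - 1) for r, c in _compress(traced))
        touches = bool(
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        contours.append(
            Contour(points=pts, bbox=(r0, c0, r1, c1), touches_border=touches,
                    area_px=int(rows.size))
        )
    contours.sort(key=lambda ct: (ct.bbox[0], ct.bbox[1]))
    return contours


def reject_border_contours(cs: list[Contour]) -> list[Contour]:
    """Drop contours that intersect the frame edge, preserving order."""
    return [c for c in cs if not c.touches_border]
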