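"""Boundary extraction and extreme-point geometry for binary masks.

Coordinate convention used throughout the package: a point ``(x, y)``
has ``x`` = column index and ``y`` = row index, both 0-based, with ``y``
increasing downward.  Masks are sampled at pixel centers, so the pixel
at row r, column c covers the square ``[c - 0.5, c + 0.5] x [r - 0.5,
r + 0.5]`` and the traced object boundary runs along the 0.5 iso-level
between foreground and background, giving sub-pixel coordinates.

Contours are oriented so that the four extreme points appear in the
fixed traversal order top -> leftmost -> bottom -> rightmost, which
makes arc order deterministic for the piecewise encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .errors import DegenerateObjectError

__all__ = [
    "ExtremePoints",
    "extract_contour",
    "find_extreme_points",
    "split_contour",
    "smooth_mask",
    "resample_polyline",
]


def as_bool_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if m.dtype != bool:
        m = m > 0
    return m


def shoelace_sum(points: np.ndarray) -> float:
    """Twice the signed polygon area, sum(x_i y_{i+1} - x_{i+1} y_i)."""
    x, y = points[:, 0], points[:, 1]
    return float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class ExtremePoints:
    """The top / leftmost / bottom / rightmost boundary points.

    ``indices`` locates each point on the contour it was derived from,
    in traversal order (top, leftmost, bottom, rightmost).
    """

    top: np.ndarray
    leftmost: np.ndarray
    bottom: np.ndarray
    rightmost: np.ndarray
    indices: tuple[int, int, int, int]

    @property
    def points(self) -> np.ndarray:
        return np.stack([self.top, self.leftmost, self.bottom, self.rightmost])


def extract_contour(mask) -> np.ndarray:
    """Trace the closed sub-pixel boundary of the largest object in a mask.

    The mask is reduced to its largest 8-connected component (ties broken
    by earliest raster-scan position), holes are filled, and the boundary
    is traced at the 0.5 iso-level after padding with one background
    pixel (so full-frame objects still yield a closed contour).

    Returns
    -------
    ndarray of shape (m, 2)
        ``(x, y)`` points tracing the boundary once; the last point
        connects implicitly back to the first.  No consecutive
        duplicates.  Orientation is fixed (see module docstring).
    """
    m = as_bool_mask(mask)
    if not m.any():
        raise DegenerateObjectError("cannot extract a contour from an empty mask")

    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        # argmax returns the first maximum; scipy labels components in
        # raster order, so ties go to the earliest-scanned component.
        m = labels == (int(np.argmax(counts)) + 1)
    m = ndimage.binary_fill_holes(m)

    padded = np.pad(m, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise DegenerateObjectError("no boundary found")
    rc = max(contours, key=len)
    pts = rc[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding offset

    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # drop consecutive duplicates (cyclically)
    prev = np.roll(pts, 1, axis=0)
    keep = np.any(np.abs(pts - prev) > 1e-12, axis=1)
    pts = pts[keep]

    if pts.shape[0] < 4:
        raise DegenerateObjectError(
            f"object boundary has only {pts.shape[0]} points; need >= 4"
        )
    if shoelace_sum(pts) > 0:
        pts = pts[::-1]
    return np.ascontiguousarray(pts)


def find_extreme_points(contour: np.ndarray) -> ExtremePoints:
    """Locate the four extreme points with deterministic tie-breaking.

    When several boundary points attain an extreme, the corner rule picks
    - top: the top-left of the topmost points (min y, then min x),
    - leftmost: the bottom-left (min x, then max y),
    - bottom: the bottom-right (max y, then max x),
    - rightmost: the top-right (max x, then min y),
    so for an axis-aligned rectangle the four chosen points are its four
    corners, in traversal order.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise DegenerateObjectError("contour must contain at least 4 points")
    x, y = pts[:, 0], pts[:, 1]

    def pick(primary, prefer_min_primary, secondary, prefer_min_secondary):
        cand = np.flatnonzero(
            primary == (primary.min() if prefer_min_primary else primary.max())
        )
        s = secondary[cand]
        best = s.argmin() if prefer_min_secondary else s.argmax()
        return int(cand[best])

    i_top = pick(y, True, x, True)
    i_left = pick(x, True, y, False)
    i_bottom = pick(y, False, x, False)
    i_right = pick(x, False, y, True)
    indices = (i_top, i_left, i_bottom, i_right)

    if len(set(indices)) != 4:
        raise DegenerateObjectError(
            "fewer than four distinct extreme points; object too degenerate"
        )
    # Extreme points lie on the convex hull, so a simple closed contour
    # visits them in hull order; verify the traversal order is
    # top -> leftmost -> bottom -> rightmost under the fixed orientation.
    n = pts.shape[0]
    rel = [(i - i_top) % n for i in indices]
    if not (rel[0] < rel[1] < rel[2] < rel[3]):
        raise DegenerateObjectError(
            "extreme points out of traversal order; contour is not a "
            "simple object boundary"
        )
    return ExtremePoints(
        top=pts[i_top].copy(),
        leftmost=pts[i_left].copy(),
        bottom=pts[i_bottom].copy(),
        rightmost=pts[i_right].copy(),
        indices=indices,
    )


def split_contour(contour: np.ndarray, extremes: ExtremePoints) -> list[np.ndarray]:
    """Cut the contour into four arcs at the extreme points.

    Arc k starts at extreme point k and ends at extreme point k+1
    (cyclically), endpoints inclusive, so consecutive arcs share exactly
    one point and ``sum(len(arc) - 1) == len(contour)``.
    """
    pts = np.asarray(contour, dtype=float)
    n = pts.shape[0]
    idx = list(extremes.indices)
    if len(set(idx)) != 4:
        raise DegenerateObjectError("extreme-point indices must be distinct")
    arcs = []
    for a, b in zip(idx, idx[1:] + idx[:1]):
        if b > a:
            arcs.append(pts[a : b + 1].copy())
        else:
            arcs.append(np.concatenate([pts[a:], pts[: b + 1]], axis=0))
    return arcs


def smooth_mask(mask, radius: int) -> np.ndarray:
    """Morphological opening then closing with a disk structuring element.

    Removes spikes and thin protrusions along the object boundary before
    fitting.  ``radius == 0`` is the identity.
    """
    m = as_bool_mask(mask)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return m.copy()
    selem = morphology.disk(int(radius))
    out = morphology.closing(morphology.opening(m, selem), selem)
    if not out.any():
        raise DegenerateObjectError(
            f"morphological smoothing with radius {radius} erased the object"
        )
    return out


def resample_polyline(points: np.ndarray, m: int) -> np.ndarray:
    """Resample an open polyline to ``m`` points uniform in arc length.

    Endpoints are preserved exactly.  Used to densify tiny arcs before a
    least-squares fit.
    """
    pts = np.asarray(points, dtype=float)
    if m < 2:
        raise ValueError("need at least 2 output points")
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:  # all points coincident
        return np.repeat(pts[:1], m, axis=0)
    u = np.linspace(0.0, s[-1], m)
    x = np.interp(u, s, pts[:, 0])
    y = np.interp(u, s, pts[:, 1])
    out = np.column_stack([x, y])
    out[0], out[-1] = pts[0], pts[-1]
    return out
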