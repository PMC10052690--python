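"""Shape codec: constrained Bezier fitting, packing, decoding, rasterizing.

An object's boundary is split at its four extreme points and each arc is
fitted with one degree-n Bezier curve whose first and last control
points are pinned to the arc's endpoints.  With the arc's m points
assigned parameters t_i = (i - 1)/(m - 1), the Bernstein basis matrix
reduces (after removing the two endpoint rows and moving the endpoint
columns to the right-hand side) to a linear system A c = b whose
minimum-norm least-squares solution c = A+ b gives the interior control
points.  Both coordinates share the basis matrix and are solved in one
system.

The resulting shape code is the flat vector

    [4 extreme points (traversal order), then the 4 x (n-1) interior
     control points segment by segment], each point as (x, y)

of length (4 + 4(n-1)) * 2 = 40 for the default degree n = 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bezier import BezierSegment, bernstein_matrix
from .contour import (
    extract_contour,
    find_extreme_points,
    resample_polyline,
    smooth_mask,
    split_contour,
)
from .errors import CodecError, UnderdeterminedArcError

__all__ = [
    "ShapeCode",
    "PiecewiseShape",
    "fit_segment",
    "encode",
    "decode",
    "rasterize",
]

#: SVD relative cutoff for the pseudo-inverse; robust for near-degenerate arcs.
PINV_RCOND = 1e-10


@dataclass(frozen=True)
class ShapeCode:
    """Flat coordinate vector encoding one piecewise Bezier shape.

    ``values`` has length ``(4 + 4*(degree-1)) * 2`` (40 at the default
    degree 5): the 4 extreme points in traversal order followed by the
    interior control points of the four segments, each point stored as
    consecutive (x, y).
    """

    values: np.ndarray = field()
    degree: int = 5

    NE = 4  # number of extreme points / segments

    def __post_init__(self):
        if self.degree < 2:
            raise CodecError("shape codes need degree >= 2")
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.length(self.degree):
            raise CodecError(
                f"shape code for degree {self.degree} must have "
                f"{self.length(self.degree)} values, got {v.size}"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @staticmethod
    def length(degree: int) -> int:
        return (4 + 4 * (degree - 1)) * 2

    @property
    def nc(self) -> int:
        """Number of interior control points (16 at degree 5)."""
        return 4 * (self.degree - 1)

    def points(self) -> np.ndarray:
        """All code points as a ``(4 + nc, 2)`` array (extremes first)."""
        return self.values.reshape(-1, 2)

    def extreme_points(self) -> np.ndarray:
        return self.points()[:4]

    def segments(self) -> "PiecewiseShape":
        pts = self.points()
        ext, ctrl = pts[:4], pts[4:]
        ni = self.degree - 1
        segs = []
        for k in range(4):
            interior = ctrl[k * ni : (k + 1) * ni]
            cp = np.vstack([ext[k], interior, ext[(k + 1) % 4]])
            segs.append(BezierSegment(cp))
        return PiecewiseShape(tuple(segs))

    def translated(self, dx: float, dy: float) -> "ShapeCode":
        return ShapeCode(self.values + np.tile([dx, dy], self.values.size // 2),
                         degree=self.degree)

    # ---- JSON interchange ------------------------------------------------
    def to_json(self, **extra) -> str:
        payload = {
            "ne": 4,
            "nc": self.nc,
            "degree": self.degree,
            "order": "extremes_then_controls",
            "values": self.values.tolist(),
        }
        payload.update(extra)
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ShapeCode":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CodecError(f"invalid shape-code JSON: {exc}") from exc
        try:
            degree = int(payload["degree"])
            values = np.asarray(payload["values"], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise CodecError("shape-code JSON missing degree/values") from exc
        if payload.get("order", "extremes_then_controls") != "extremes_then_controls":
            raise CodecError(f"unsupported code ordering {payload.get('order')!r}")
        if values.size != cls.length(degree):
            raise CodecError(
                f"shape-code JSON has {values.size} values, expected "
                f"{cls.length(degree)} for degree {degree}"
            )
        return cls(values, degree=degree)


@dataclass(frozen=True)
class PiecewiseShape:
    """Four Bezier segments of common degree sharing their endpoints."""

    segments: tuple[BezierSegment, BezierSegment, BezierSegment, BezierSegment]

    def __post_init__(self):
        if len(self.segments) != 4:
            raise CodecError("a piecewise shape has exactly 4 segments")
        degs = {s.degree for s in self.segments}
        if len(degs) != 1:
            raise CodecError(f"segments must share one degree, got {degs}")
        for k in range(4):
            a = self.segments[k].control_points[-1]
            b = self.segments[(k + 1) % 4].control_points[0]
            if not np.allclose(a, b, atol=1e-9):
                raise CodecError("consecutive segments must share an endpoint")

    @property
    def degree(self) -> int:
        return self.segments[0].degree

    def to_code(self) -> ShapeCode:
        ext = np.stack([s.control_points[0] for s in self.segments])
        interior = np.concatenate([s.control_points[1:-1] for s in self.segments])
        return ShapeCode(np.concatenate([ext, interior]).ravel(),
                         degree=self.degree)


def fit_segment(arc: np.ndarray, degree: int = 5,
                parametrization: str = "index") -> BezierSegment:
    """Fit a degree-n Bezier to an arc with pinned endpoints.

    Parameters are assigned by index fraction ``t_i = (i-1)/(m-1)``
    (``parametrization="index"``, the default) or by normalized chord
    length (``"chord"``).  The interior control points are the
    minimum-norm least-squares solution ``c = A+ b`` with the
    pseudo-inverse computed by SVD (relative cutoff 1e-10).
    """
    pts = np.asarray(arc, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("arc must be an (m, 2) array")
    m = pts.shape[0]
    if m < degree + 1:
        raise UnderdeterminedArcError(
            f"arc with {m} points underdetermines a degree-{degree} fit "
            f"(need >= {degree + 1}); resample the arc first"
        )
    if parametrization == "index":
        ts = np.linspace(0.0, 1.0, m)
    elif parametrization == "chord":
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        ts = s / s[-1] if s[-1] > 0 else np.linspace(0.0, 1.0, m)
    else:
        raise ValueError(f"unknown parametrization {parametrization!r}")

    basis = bernstein_matrix(degree, ts)            # (m, n+1)
    A = basis[1:-1, 1:-1]                           # interior rows x cols
    b = (
        pts[1:-1]
        - np.outer(basis[1:-1, 0], pts[0])
        - np.outer(basis[1:-1, -1], pts[-1])
    )
    interior = np.linalg.pinv(A, rcond=PINV_RCOND) @ b
    return BezierSegment(np.vstack([pts[0], interior, pts[-1]]))


def encode(mask, degree: int = 5, smooth_radius: int = 0,
           parametrization: str = "index") -> ShapeCode:
    """Encode a single-object binary mask as a piecewise Bezier shape code.

    Pipeline: optional morphological smoothing -> sub-pixel contour
    extraction -> extreme-point location -> split into four arcs -> one
    constrained fit per arc -> pack.  Arcs shorter than ``degree + 1``
    points are linearly resampled to ``2 * (degree + 1)`` points first.
    Deterministic.
    """
    if smooth_radius:
        mask = smooth_mask(mask, smooth_radius)
    contour = extract_contour(mask)
    extremes = find_extreme_points(contour)
    arcs = split_contour(contour, extremes)
    segments = []
    for arc in arcs:
        if arc.shape[0] < degree + 1:
            arc = resample_polyline(arc, 2 * (degree + 1))
        segments.append(fit_segment(arc, degree, parametrization))
    return PiecewiseShape(tuple(segments)).to_code()


def decode(code: ShapeCode, samples_per_segment: int = 72) -> np.ndarray:
    """Sample a shape code back to a dense closed contour.

    Each segment is sampled on a uniform t grid of ``samples_per_segment``
    points; shared endpoints are emitted once, so the result has
    ``4 * (samples_per_segment - 1)`` points.
    """
    if samples_per_segment < 2:
        raise ValueError("samples_per_segment must be >= 2")
    shape = code.segments()
    ts = np.linspace(0.0, 1.0, samples_per_segment)
    basis = bernstein_matrix(code.degree, ts)
    pieces = [(basis @ seg.control_points)[:-1] for seg in shape.segments]
    return np.concatenate(pieces, axis=0)


def rasterize(contour: np.ndarray, height: int, width: int) -> np.ndarray:
    """Scan-fill a closed contour into a boolean mask.

    A pixel is foreground when its center lies inside the polygon under
    the even-odd rule, or exactly on a non-horizontal boundary edge.
    Self-intersecting contours are therefore filled even-odd.  Pixel
    centers sit at integer coordinates.
    """
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    pts = np.asarray(contour, dtype=float)
    mask = np.zeros((height, width), dtype=bool)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        return mask
    if not np.all(np.isfinite(pts)):
        return mask

    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    ylo, yhi = np.minimum(y1, y2), np.maximum(y1, y2)
    # integer rows r with ylo <= r < yhi (half-open: vertex rows counted once)
    r0 = np.maximum(np.ceil(ylo), 0.0)
    r1 = np.minimum(np.ceil(yhi) - 1.0, height - 1.0)
    counts = (r1 - r0 + 1.0).clip(min=0.0).astype(int)
    total = int(counts.sum())
    if total == 0:
        return mask

    edge = np.repeat(np.arange(pts.shape[0]), counts)
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    rows = (np.repeat(r0, counts) + (np.arange(total) - starts)).astype(int)
    denom = y2[edge] - y1[edge]
    xint = x1[edge] + (rows - y1[edge]) * (x2[edge] - x1[edge]) / denom
    # snap intersections that hit a pixel center up to fp noise, so the
    # boundary-center-is-foreground rule is insensitive to roundoff
    xr = np.round(xint)
    xint = np.where(np.abs(xint - xr) < 1e-9, xr, xint)

    # Even-odd parity of crossings strictly right of the center (iA) and
    # right-or-on it (iB); a center is inside when either parity is odd,
    # which also keeps centers lying exactly on a vertical edge.
    iA = np.ceil(xint).astype(int) - 1   # crossings with xint >  c cover c <= iA
    iB = np.floor(xint).astype(int)      # crossings with xint >= c cover c <= iB
    histA = np.zeros((height, width), dtype=np.int64)
    histB = np.zeros((height, width), dtype=np.int64)
    selA = iA >= 0
    np.add.at(histA, (rows[selA], np.minimum(iA[selA], width - 1)), 1)
    selB = iB >= 0
    np.add.at(histB, (rows[selB], np.minimum(iB[selB], width - 1)), 1)
    cntA = np.cumsum(histA[:, ::-1], axis=1)[:, ::-1]
    cntB = np.cumsum(histB[:, ::-1], axis=1)[:, ::-1]
    return (cntA % 2 == 1) | (cntB % 2 == 1)
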