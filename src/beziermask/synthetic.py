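"""Synthetic single-object binary masks for testing and experiments.

Generates masks that emulate the region-of-interest regimes seen in
medical segmentation data: smooth star-convex blobs of controlled area
(ellipse, superellipse, Fourier blob, square) plus a dumbbell as a
non-star-convex stressor — the shape family where polar/ray encodings
break because a ray from the centroid crosses the boundary more than
once.  Shapes are rasterized from their analytic implicit form at pixel
centers (equivalent to anti-aliased rendering thresholded at 0.5), so
star-convex kinds come with an analytic ground-truth contour.

The size regimes for batteries mirror typical lesion datasets: mean
areas of roughly 745 px (small), 14,152 px (medium) and 29,337 px
(large).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import gamma

from .errors import BezierMaskError

__all__ = ["ShapeSpec", "generate", "generate_battery", "REGIME_AREAS"]

REGIME_AREAS = {"small": 745, "medium": 14152, "large": 29337}

KINDS = ("ellipse", "superellipse", "fourier_blob", "dumbbell", "square")


class ShapeSpecError(BezierMaskError, ValueError):
    pass


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one synthetic mask.

    ``smoothness`` is the number of Fourier harmonics for blobs (higher
    = wigglier boundary); harmonic amplitudes are bounded by 0.2/h so
    the radius stays positive and the shape star-convex.
    """

    kind: str
    area_target: float
    height: int = 256
    width: int = 256
    smoothness: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ShapeSpecError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if self.area_target < 50:
            raise ShapeSpecError("area_target must be >= 50 pixels")
        if self.height < 8 or self.width < 8:
            raise ShapeSpecError("image too small")
        if self.smoothness < 1:
            raise ShapeSpecError("smoothness must be >= 1")


def _grid(spec: ShapeSpec, center, angle):
    ys, xs = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    dx, dy = xs - center[0], ys - center[1]
    c, s = np.cos(angle), np.sin(angle)
    return c * dx + s * dy, -s * dx + c * dy  # rotated local coords (u, v)


def _rot(points, center, angle):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return points @ R.T + np.asarray(center)


def _fit_radius(spec: ShapeSpec, center) -> float:
    margin = 3.0
    return min(center[0], center[1],
               spec.width - 1 - center[0], spec.height - 1 - center[1]) - margin


def generate(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray | None]:
    """Build one mask (and its analytic contour when the kind has one).

    Returns ``(mask, contour)`` where ``mask`` is a boolean (H, W) array
    with a single hole-free connected component whose area is within
    15% of ``spec.area_target``, and ``contour`` is a dense ``(m, 2)``
    array of analytic boundary points, or ``None`` for the dumbbell.
    Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.array([spec.width / 2.0, spec.height / 2.0]) + rng.uniform(-3, 3, 2)
    angle = rng.uniform(0.0, np.pi)
    rmax = _fit_radius(spec, center)
    if rmax <= 2.0:
        raise ShapeSpecError("image leaves no room for the shape")
    area = float(spec.area_target)
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)

    if spec.kind == "ellipse":
        q = rng.uniform(1.2, 1.8)
        q = min(q, max(1.0, rmax**2 * np.pi / area))
        a = np.sqrt(q * area / np.pi)
        if a > rmax:
            raise ShapeSpecError("area_target unreachable in frame")
        b = a / q
        u, v = _grid(spec, center, angle)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        local = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        contour = _rot(local, center, angle)

    elif spec.kind == "superellipse":
        p = rng.uniform(2.5, 4.0)
        # area of |x/a|^p + |y/b|^p <= 1 is 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)
        g = 4.0 * gamma(1.0 + 1.0 / p) ** 2 / gamma(1.0 + 2.0 / p)
        q = rng.uniform(1.1, 1.5)
        a = np.sqrt(q * area / g)
        if a > rmax:
            q = max(1.0, g * rmax**2 / area * 0.98)
            a = np.sqrt(q * area / g)
            if a > rmax:
                raise ShapeSpecError("area_target unreachable in frame")
        b = a / q
        u, v = _grid(spec, center, angle)
        mask = np.abs(u / a) ** p + np.abs(v / b) ** p <= 1.0
        ct, st = np.cos(theta), np.sin(theta)
        local = np.column_stack([
            a * np.sign(ct) * np.abs(ct) ** (2.0 / p),
            b * np.sign(st) * np.abs(st) ** (2.0 / p),
        ])
        contour = _rot(local, center, angle)

    elif spec.kind == "fourier_blob":
        harmonics = np.arange(2, 2 + spec.smoothness)
        amps = rng.uniform(-0.2 / harmonics, 0.2 / harmonics)
        phases = rng.uniform(0.0, 2.0 * np.pi, harmonics.size)
        # mean of r(theta)^2 over theta is r0^2 (1 + sum a_h^2 / 2)
        r0 = np.sqrt(area / (np.pi * (1.0 + np.sum(amps**2) / 2.0)))
        if r0 * (1.0 + np.sum(np.abs(amps))) > rmax:
            raise ShapeSpecError("area_target unreachable in frame")
        u, v = _grid(spec, center, angle)
        th = np.arctan2(v, u)
        rad = r0 * (1.0 + sum(a * np.cos(h * th + ph)
                              for a, h, ph in zip(amps, harmonics, phases)))
        mask = u**2 + v**2 <= rad**2
        r_th = r0 * (1.0 + sum(a * np.cos(h * theta + ph)
                               for a, h, ph in zip(amps, harmonics, phases)))
        local = np.column_stack([r_th * np.cos(theta), r_th * np.sin(theta)])
        contour = _rot(local, center, angle)

    elif spec.kind == "square":
        side = np.sqrt(area)
        if side / 2.0 > rmax:
            raise ShapeSpecError("area_target unreachable in frame")
        # axis-aligned with a sub-pixel offset, to exercise flat-edge ties
        off = rng.uniform(0.0, 1.0, 2)
        x0, y0 = center[0] - side / 2.0 + off[0], center[1] - side / 2.0 + off[1]
        ys, xs = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
        mask = (xs >= x0) & (xs <= x0 + side) & (ys >= y0) & (ys <= y0 + side)
        contour = np.array([
            [x0, y0], [x0, y0 + side], [x0 + side, y0 + side], [x0 + side, y0],
        ])

    elif spec.kind == "dumbbell":
        # two lobes of radius r at +-1.8 r along the local axis, joined by a
        # neck of half-height 0.35 r; the pinch is deep enough that rays from
        # the centroid cross the boundary three times at shallow angles.
        # Unit-shape area found by quadrature.
        sep, neck = 1.8, 0.35
        gx, gy = np.meshgrid(np.linspace(-3.0, 3.0, 601),
                             np.linspace(-1.2, 1.2, 241))
        inside = (
            ((gx - sep) ** 2 + gy**2 <= 1.0)
            | ((gx + sep) ** 2 + gy**2 <= 1.0)
            | ((np.abs(gx) <= sep) & (np.abs(gy) <= neck))
        )
        unit_area = inside.mean() * (6.0 * 2.4)
        r = np.sqrt(area / unit_area)
        if r * (sep + 1.0) > rmax:
            raise ShapeSpecError("area_target unreachable in frame")
        u, v = _grid(spec, center, angle)
        mask = (
            ((u - sep * r) ** 2 + v**2 <= r**2)
            | ((u + sep * r) ** 2 + v**2 <= r**2)
            | ((np.abs(u) <= sep * r) & (np.abs(v) <= neck * r))
        )
        contour = None

    got = int(mask.sum())
    if not (0.85 * area <= got <= 1.15 * area):
        raise ShapeSpecError(
            f"generated area {got} misses target {area:.0f} by more than 15%"
        )
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ShapeSpecError(f"generated mask has {n_comp} components")
    return mask, contour


def generate_battery(
    n: int,
    regime: str,
    seed: int = 0,
    kinds: tuple[str, ...] = ("ellipse", "fourier_blob", "superellipse"),
) -> list[np.ndarray]:
    """A battery of n masks with areas drawn around the regime mean (+-30%).

    Kinds cycle through the smooth star-convex family by default; the
    dumbbell stressor is generated separately via :func:`generate`.
    Images are 256x256 for the small/medium regimes and 384x384 for the
    large regime (so high-aspect large shapes always fit).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime not in REGIME_AREAS:
        raise ValueError(f"unknown regime {regime!r}; choose from {list(REGIME_AREAS)}")
    mean = REGIME_AREAS[regime]
    size = 384 if regime == "large" else 256
    rng = np.random.default_rng(seed)
    masks = []
    for i in range(n):
        area = mean * rng.uniform(0.7, 1.3)
        spec = ShapeSpec(
            kind=kinds[i % len(kinds)],
            area_target=area,
            height=size,
            width=size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        masks.append(generate(spec)[0])
    return masks
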