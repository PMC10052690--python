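"""Exact Bezier curve mathematics.

A degree-n Bezier curve is defined by n + 1 control points P_0 .. P_n
through the Bernstein basis

    B(t) = sum_i  C(n, i) (1 - t)^(n-i) t^i  P_i,      t in [0, 1].

The curve interpolates its first and last control points, lies inside the
convex hull of the control polygon, and is affine-equivariant.  Two
evaluation routes are provided: the explicit Bernstein form and De
Casteljau's repeated-linear-interpolation construction; they agree to
machine precision and serve as cross-checks of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "BezierSegment",
    "bernstein_matrix",
    "evaluate_bernstein",
    "evaluate_decasteljau",
    "sample_curve",
]


@dataclass(frozen=True)
class BezierSegment:
    """One degree-n Bezier curve given by its ordered control points.

    Parameters
    ----------
    control_points
        Sequence of n + 1 points ``(x, y)`` in pixel units.
    """

    control_points: np.ndarray = field()

    def __post_init__(self):
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError(
                "control_points must be an (n+1, 2) array with n >= 1, "
                f"got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("control points must be finite")
        pts.setflags(write=False)
        object.__setattr__(self, "control_points", pts)

    @property
    def degree(self) -> int:
        return self.control_points.shape[0] - 1


def _check_ts(ts: np.ndarray) -> np.ndarray:
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    if ts.size == 0:
        raise ValueError("parameter sequence is empty")
    if np.any(~np.isfinite(ts)) or np.any(ts < 0.0) or np.any(ts > 1.0):
        raise ValueError("curve parameter t must lie in [0, 1]")
    return ts


def bernstein_matrix(degree: int, ts: Sequence[float]) -> np.ndarray:
    """Bernstein basis matrix ``B[i, j] = C(n, j) (1-t_i)^(n-j) t_i^j``.

    Binomial coefficients are computed exactly as integers before the
    cast to float; ``0**0`` terms at the endpoints evaluate to 1 as
    required by the basis convention.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    ts = _check_ts(ts)
    j = np.arange(degree + 1)
    coeff = np.array([comb(degree, k) for k in j], dtype=float)
    t = ts[:, None]
    # 0.0 ** 0 == 1.0 in IEEE arithmetic, so the endpoint rows come out
    # as exact unit vectors without special-casing.
    return coeff * (1.0 - t) ** (degree - j) * t**j


def evaluate_bernstein(segment: BezierSegment, t: float) -> np.ndarray:
    """Evaluate the curve at parameter ``t`` via the explicit Bernstein sum."""
    ts = _check_ts(t)
    if ts.size != 1:
        raise ValueError("evaluate_bernstein takes a scalar t; use sample_curve")
    t = float(ts[0])
    # Endpoint short-circuit: exact interpolation, no rounding in the basis.
    if t == 0.0:
        return segment.control_points[0].copy()
    if t == 1.0:
        return segment.control_points[-1].copy()
    basis = bernstein_matrix(segment.degree, [t])
    return (basis @ segment.control_points)[0]


def evaluate_decasteljau(segment: BezierSegment, t: float) -> np.ndarray:
    """Evaluate the curve at ``t`` by De Casteljau's construction.

    Repeatedly insert intermediate points on every leg of the control
    polygon at ratio ``t : 1 - t`` and treat them as the new control
    points, until a single point remains.
    """
    ts = _check_ts(t)
    if ts.size != 1:
        raise ValueError("evaluate_decasteljau takes a scalar t")
    t = float(ts[0])
    pts = segment.control_points.copy()
    while pts.shape[0] > 1:
        pts = (1.0 - t) * pts[:-1] + t * pts[1:]
    return pts[0]


def sample_curve(segment: BezierSegment, ts: Sequence[float]) -> np.ndarray:
    """Evaluate the curve at every parameter in ``ts`` (order preserved)."""
    ts = _check_ts(ts)
    return bernstein_matrix(segment.degree, ts) @ segment.control_points
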