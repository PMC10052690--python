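"""Segmentation comparison metrics between masks and contours."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .contour import as_bool_mask
from .errors import BezierMaskError

__all__ = ["MaskComparison", "mask_iou", "mask_confusion", "hausdorff"]


class MetricError(BezierMaskError, ValueError):
    pass


@dataclass(frozen=True)
class MaskComparison:
    """Pixel-level confusion counts and the derived scores.

    ``mcc`` is the Matthews correlation coefficient, defined as 0 when a
    marginal is empty (all-positive or all-negative prediction or truth);
    ``fp_rate = fp / (fp + tn)`` and ``fn_rate = fn / (fn + tp)``, each 0
    when its denominator is 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def iou(self) -> float:
        union = self.tp + self.fp + self.fn
        return 1.0 if union == 0 else self.tp / union

    @property
    def mcc(self) -> float:
        tp, fp, fn, tn = (float(v) for v in (self.tp, self.fp, self.fn, self.tn))
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0.0:
            return 0.0
        return (tp * tn - fp * fn) / np.sqrt(denom)

    @property
    def fp_rate(self) -> float:
        return 0.0 if self.fp + self.tn == 0 else self.fp / (self.fp + self.tn)

    @property
    def fn_rate(self) -> float:
        return 0.0 if self.fn + self.tp == 0 else self.fn / (self.fn + self.tp)


def _pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p, t = as_bool_mask(pred), as_bool_mask(truth)
    if p.shape != t.shape:
        raise MetricError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return p, t


def mask_iou(pred, truth) -> float:
    """Intersection over union of two foreground pixel sets (1.0 if both empty)."""
    p, t = _pair(pred, truth)
    union = int(np.count_nonzero(p | t))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(p & t)) / union


def mask_confusion(pred, truth) -> MaskComparison:
    """Pixel confusion counts of a predicted mask against a reference."""
    p, t = _pair(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return MaskComparison(tp=tp, fp=fp, fn=fn, tn=tn)


def hausdorff(pred_contour, truth_contour) -> float:
    """Symmetric Hausdorff distance between two contour point sets, in pixels.

    Computed between the sampled boundary points (at whatever density the
    caller decoded them), not between rasterized mask boundaries.
    """
    a = np.asarray(pred_contour, dtype=float)
    b = np.asarray(truth_contour, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricError("hausdorff distance of an empty contour is undefined")
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
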