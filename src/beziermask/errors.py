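"""Exception hierarchy for the beziermask package."""


class BezierMaskError(Exception):
    """Base class for all package-specific errors."""


class DegenerateObjectError(BezierMaskError, ValueError):
    """Mask or contour is too small / too degenerate to encode.

    Raised for empty masks, objects whose boundary has fewer than four
    points, objects erased by morphological smoothing, and contours on
    which four distinct extreme points cannot be placed.
    """


class UnderdeterminedArcError(BezierMaskError, ValueError):
    """An arc has fewer points than a degree-n fit needs (m < n + 1).

    Callers should densify the arc (e.g. resample the polyline) before
    fitting; :func:`beziermask.codec.encode` does this automatically.
    """


class CodecError(BezierMaskError, ValueError):
    """Malformed shape code (wrong length, bad JSON payload, ...)."""


class OptimizationError(BezierMaskError, RuntimeError):
    """Gradient descent on the shape-code loss diverged.

    The loss trajectory up to the failure is attached as ``trajectory``.
    """

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory
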