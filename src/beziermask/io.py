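"""Reading and writing masks, contours and shape codes on disk.

Masks travel as 8-bit grayscale PNG with 0 = background and 255 =
foreground (any value >= 128 reads as foreground).  Contours travel as
CSV with header ``x,y``, one sub-pixel point per row.  Shape codes use
the JSON layout of :meth:`beziermask.codec.ShapeCode.to_json`.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from .codec import ShapeCode

__all__ = [
    "read_mask",
    "write_mask",
    "read_contour_csv",
    "write_contour_csv",
    "read_code",
    "write_code",
]


def read_mask(path) -> np.ndarray:
    img = Image.open(path).convert("L")
    return np.asarray(img) >= 128


def write_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def write_contour_csv(path, contour: np.ndarray) -> None:
    pts = np.asarray(contour, dtype=float)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in pts:
            writer.writerow([repr(float(x)), repr(float(y))])


def read_contour_csv(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["x", "y"]:
        raise ValueError(f"{path}: expected a contour CSV with header x,y")
    return np.array([[float(x), float(y)] for x, y in rows[1:]])


def write_code(path, code: ShapeCode, **extra) -> None:
    Path(path).write_text(code.to_json(**extra) + "\n")


def read_code(path) -> ShapeCode:
    return ShapeCode.from_json(Path(path).read_text())
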