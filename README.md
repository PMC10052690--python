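# beziermask

Piecewise Bézier shape codes for single-object binary masks.

Pixel-wise segmentation of solid lesions in medical images tends to produce
glitchy, disconnected boundaries, and a dense label map is an awkward object
to transmit, refine by hand, or rescale. `beziermask` implements the
alternative: represent the object **contour** analytically, as four Bézier
curve segments joined at the object's extreme points, so the whole shape is
40 numbers. The representation is guaranteed connected, continuous and
smooth, carries sub-pixel accuracy, can be re-rasterized at any resolution
by pure coordinate scaling, and its control points are directly editable by
a human. It is aimed at people building or evaluating contour-regression
segmentation models, and at anyone who needs a compact, manipulable encoding
of single-object masks.

## The representation

A degree-*n* Bézier curve with control points *P₀ … Pₙ* is

```
B(t) = Σᵢ C(n,i) (1−t)^(n−i) tⁱ Pᵢ,   t ∈ [0, 1].
```

To encode a mask, the object boundary is traced at the 0.5 iso-level
(sub-pixel), split at its four extreme points (top, leftmost, bottom,
rightmost — deterministic corner tie-breaking on flat edges), and each of
the four arcs is fitted with a quintic (*n* = 5) Bézier whose first and last
control points are pinned to the arc's endpoints. With the arc's *m* points
assigned parameters *tᵢ = (i−1)/(m−1)*, the interior control points are the
least-squares solution *c = A⁺b* of the reduced Bernstein system. The shape
code concatenates the 4 extreme points and the 4×4 interior control points:
a 40-dimensional vector (nₑ = 4, n_c = 16).

On top of the codec the package provides:

- **metrics** — IoU, pixel confusion (MCC, fp/fn rates), symmetric Hausdorff
  distance between contours;
- **differentiable shape decoder** — a linear map from the code to N = 72
  boundary points sampled at shared uniform *t* draws, plus the two-term
  smooth-L1 training loss `L = λce·Lce + λmatching·Lmatching` (both weights
  1) with exact analytic gradients and a gradient-descent demonstrator;
- **sensitivity analysis** — Gaussian noise N(0, δ²) on all 20 code points
  versus an equal-complexity 20-point polygon baseline;
- **synthetic shapes** — ellipse / superellipse / Fourier-blob / square /
  dumbbell generators with controlled area, so everything is testable
  without any dataset.

## Worked example

```bash
python examples/01_encode_decode.py
```

```
mask area: 13994 px
shape code length: 40 (degree 5)
extreme points (top, left, bottom, right):
[[134.   60.5]
 [ 66.5 140. ]
 [130.  206.5]
 [197.5 131. ]]
decoded contour points: 284
round-trip IoU vs source mask: 0.9966
```

A ~14,000-px smooth blob is compressed to 40 numbers and reconstructed at
99.7% IoU — the piecewise quintic code is nearly lossless for smooth
single-object masks. `examples/04_sensitivity.py` runs the noise experiment:

```
delta  bezier_iou  polygon_iou
    0      0.9974       0.9839
    5      0.9293       0.9067
   10      0.8624       0.8218
   20      0.7463       0.6647
```

The Bézier curve averages coordinate noise along each segment, so it stays
above the polygon baseline at every noise level. The other examples cover
metrics, the differentiable decoder loss, and the shape generator (including
the dumbbell case that single-valued polar/ray encodings cannot represent).

There is also a thin CLI (`beziermask generate|encode|decode|metrics|
sensitivity|demo-optimize|degree-sweep`); run `beziermask --help`.

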