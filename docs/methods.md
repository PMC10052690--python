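# Methods

## The shape model

A single solid object in a binary mask is represented by four Bézier curve
segments of common degree *n* (default 5) joined end-to-end at the object's
four extreme points. Bézier curves are used in Bernstein form,

    B(t) = Σ_{i=0..n} C(n,i) (1−t)^{n−i} t^i P_i,  t ∈ [0,1],

with the binomial coefficients computed exactly as integers (degrees up to 9
are supported; no overflow concerns) and evaluation at t = 0 and t = 1
short-circuited to the endpoints so the 0⁰ convention never matters. De
Casteljau's repeated-interpolation construction is implemented independently
and agrees with the Bernstein sum to ~1e-14; the two serve as mutual
oracles in the test suite.

Assumptions inherited from the model: one connected, hole-free object per
mask (the largest component is kept, holes are filled), and a boundary
smooth enough that four quintic arcs capture it. Disconnected objects and
boundary topology with holes are out of scope by design.

### Coordinates, contours, extreme points

Points are (x, y) = (column, row), 0-based, y increasing downward; masks are
sampled at pixel centers. The boundary is traced at the 0.5 iso-level with
`skimage.measure.find_contours` after padding by one background pixel, which
yields sub-pixel vertices and also handles objects touching the frame.
Contours are oriented so the traversal visits top → leftmost → bottom →
rightmost (equivalently, the shoelace sum Σ(xᵢy_{i+1} − x_{i+1}yᵢ) is
negative in this y-down frame). Extreme points on flat edges are
tie-broken to corners: top → top-left, leftmost → bottom-left, bottom →
bottom-right, rightmost → top-right, which makes the four chosen points of
an axis-aligned rectangle its four corners in traversal order. Extreme
points of a simple closed curve lie on its convex hull, so this cyclic
order is well defined; contours that violate it are rejected as degenerate.

### Constrained least-squares fit

For an arc of m points with parameters tᵢ = (i−1)/(m−1), the Bernstein
basis matrix has exact unit first and last rows; removing them and moving
the two endpoint columns to the right-hand side leaves the reduced system
A c = b for the n−1 interior control points, solved by the SVD
pseudo-inverse with relative cutoff 1e-10 (robust on nearly collinear
arcs). Both coordinates share A and are solved in one call — numerically
identical to separate fits. Design choices:

- **Index parametrization by default.** tᵢ by index fraction, not chord
  length. Chord-length parametrization usually fits slightly better and is
  available via `parametrization="chord"`, but index assignment is the
  reference behavior.
- **Tiny arcs.** An arc with fewer than n+1 points underdetermines the fit;
  `fit_segment` raises, and `encode` linearly resamples such arcs to
  2(n+1) points first.
- The fitting residual is non-increasing in the degree on a fixed arc
  (nested polynomial spaces); this is asserted for n ∈ {3, 5, 7, 9}.

### Decoding and rasterization

Decoding samples each segment on a uniform t grid (default 72 per segment)
and concatenates the four polylines without duplicating shared endpoints.
Rasterization is a vectorized even-odd scanline fill over pixel centers
with an explicit contract: a pixel is foreground iff its center is inside
the polygon under the even-odd rule, or lies exactly on a non-horizontal
edge (intersections within 1e-9 of a center are snapped, so the rule is
insensitive to floating-point noise). Self-intersecting decoded contours —
which arise under heavy coordinate noise — therefore still fill
deterministically. Neither matplotlib's path logic (winding rule) nor
shapely (too slow per pixel at Monte-Carlo scale) provides this contract,
hence the in-package implementation.

Because Bézier curves are affine-equivariant, decoding at a different
resolution is pure coordinate scaling of the code; the CLI `decode`
subcommand applies the scale factors when a target size differs from the
source size recorded at encode time.

## Differentiable decoder and loss

The decoder draws N = 72 parameters uniformly from [0, 1], splits them as
evenly as possible over the four segments (72 → 18 each; how the draw is
apportioned is a free choice — an even split keeps every segment equally
supervised), and maps the code linearly to N boundary points. The same
draw is applied to prediction and target so points correspond. The loss is

    L = λce · SmoothL1(code_pred, code_true)
      + λmatching · SmoothL1(decode(code_pred), decode(code_true)),

λce = λmatching = 1, SmoothL1 the mean over coordinates of 0.5d² (|d| < 1)
else |d| − 0.5. Gradients are exact by the chain rule through the fixed
decode matrix; the kink derivative at |d| = 1 uses the one-sided value ±1,
and finite-difference validations exclude a 1e-4 neighborhood of the kinks.

`optimize_code` is a deliberately simple demonstrator (plain gradient
descent) showing the loss alone can supervise control points. By default a
fresh parameter draw is taken each step — per-iteration resampling, which
makes the objective mildly stochastic; `resample_ts=False` fixes one draw,
making the trajectory provably non-increasing for small steps. The default
step size 10 matches the ~1/40-per-coordinate scale of mean-normalized
smooth-L1 gradients: a 30 px offset is recovered well within 500 steps
while staying inside the quadratic basin's stability limit.

## Sensitivity experiment

Coordinate uncertainty of a regressing network is emulated by adding
i.i.d. N(0, δ²) offsets to **all** 20 code points (extremes and interior
controls alike), decoding, rasterizing, and scoring IoU against the clean
source mask. The baseline polygon uses 20 vertices — the same coordinate
budget — selected index-uniformly along the traced contour, anchored at the
top extreme point for determinism (for densely traced contours this is
equivalent to arc-length-uniform selection). Noise is applied in the
mask's native pixel units. Per-mask sub-seeds are spawned deterministically
from the battery seed, so results are bit-for-bit reproducible.

## Synthetic shapes

Masks are rasterized from analytic implicit forms at pixel centers
(equivalent to anti-aliased rendering thresholded at 0.5), so star-convex
kinds carry an exact analytic contour for oracle tests:

- **ellipse / superellipse** — random aspect 1.2–1.8 (1.1–1.5), random
  rotation; superellipse exponent 2.5–4; axes solved from the exact area
  formula (Γ-function form for the superellipse).
- **fourier_blob** — r(θ) = r₀(1 + Σ_h a_h cos(hθ + φ_h)), harmonics
  h = 2…5 by default, |a_h| ≤ 0.2/h so the radius stays positive and the
  blob star-convex; r₀ solved from the mean-square radius.
- **square** — axis-aligned with sub-pixel offset, exercising the flat-edge
  tie rules and exact (degree-1) representability.
- **dumbbell** — two unit lobes at ±1.8 r joined by a neck of half-height
  0.35 r; the only non-star-convex kind, sized by quadrature of the unit
  shape. The pinch guarantees some centroid rays cross the boundary three
  or more times — the configuration single-valued polar encodings cannot
  represent — while remaining encodable by the piecewise code at ~0.93 IoU.

Generated areas are verified within 15% of target; specs whose shape cannot
fit the frame raise rather than silently clamp. Battery regimes mirror
typical lesion datasets (mean areas 745 / 14,152 / 29,337 px for small /
medium / large); battery images are 256×256 except the large regime
(384×384, since a high-aspect ~38k-px ellipse does not reliably fit 256).
Batteries draw areas uniformly within ±30% of the regime mean and cycle the
smooth star-convex kinds; the dumbbell is a separate stressor. Dumbbell
fixtures in tests use area 12,000 px in a 256 frame — at ~14k px the 2.8 r
half-length can exceed the frame margin, and an error is the correct
response there, not a silently shrunk shape.

### What the generator does not emulate

Real lesion masks have rough, annotator-dependent boundaries, intensity
ambiguity, and occasional multi-lobed or annular topology. The synthetic
batteries establish correctness of the codec, metrics, loss and experiment
machinery and the *relative* robustness ordering of representations; they
do not predict absolute fidelity numbers on any clinical dataset.

## Numerical choices and degenerate inputs

- Curve parameters outside [0, 1] raise; endpoints short-circuit.
- Empty masks, sub-4-point boundaries, objects erased by smoothing, and
  coincident extreme points raise `DegenerateObjectError`.
- A code whose 20 points coincide decodes to a point contour and
  rasterizes to an empty mask (documented, not an error); noisy decodes
  that self-intersect fill even-odd; IoU of an empty prediction is 0, and
  IoU of two empty masks is defined as 1.
- MCC is defined as 0 when a confusion marginal is empty; fp/fn rates are 0
  when their denominators are 0.
- Hausdorff distance is computed between sampled contour point sets at the
  caller's decode density, not between rasterized mask boundaries.
- Largest-component ties break by earliest raster-scan position.

## Problem sizes

Defaults used by the test suite and the reproduction script: 100-shape
medium battery for fidelity; 1,000 random segments for the evaluator
cross-check; 100 code pairs for gradient checks; 50 blobs × 3 noise levels
× 20 trials for the sensitivity ordering; 20 shapes × 10 trials per regime
for the size effect; 500 optimizer steps. These sizes give Monte-Carlo
error comfortably below the asserted margins while keeping a full run in
tens of seconds.

## Known limitations

- One object per mask; holes are filled before tracing.
- Boundaries with very deep, narrow invaginations can exceed what four
  quintic arcs express (dumbbells encode at ~0.93 IoU, not ~0.997 like
  smooth blobs).
- The optimizer is a demonstrator, not a training loop: no momentum, no
  schedules, no network.
- AUC-style threshold metrics are not provided: a hard contour has no
  probabilistic pixel output, so its ROC degenerates to a single point.
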