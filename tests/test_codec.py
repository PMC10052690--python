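"""Constrained fitting, code packing, decoding and rasterization."""

import numpy as np
import pytest

from beziermask import (
    BezierSegment,
    CodecError,
    ShapeCode,
    UnderdeterminedArcError,
    decode,
    encode,
    extract_contour,
    fit_segment,
    find_extreme_points,
    hausdorff,
    mask_iou,
    rasterize,
    sample_curve,
    split_contour,
)


def brute_force_even_odd(contour, height, width):
    """Independent crossing-number oracle over all pixel centers."""
    pts = np.asarray(contour, float)
    out = np.zeros((height, width), dtype=bool)
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for r in range(height):
        cross = ((y1 <= r) & (r < y2)) | ((y2 <= r) & (r < y1))
        xi = x1[cross] + (r - y1[cross]) * (x2[cross] - x1[cross]) / (y2[cross] - y1[cross])
        for c in range(width):
            on_edge = np.any(np.isclose(xi, c, atol=1e-12))
            out[r, c] = on_edge or (np.count_nonzero(xi > c) % 2 == 1)
    return out


# ---------------------------------------------------------------- fitting

def test_exact_quintic_recovery(rng):
    """Least squares is exact when the data come from the model."""
    ctrl = rng.uniform(0, 100, size=(6, 2))
    arc = sample_curve(BezierSegment(ctrl), np.linspace(0, 1, 50))
    fitted = fit_segment(arc, degree=5)
    assert np.max(np.abs(fitted.control_points - ctrl)) <= 1e-8
    refit = sample_curve(fitted, np.linspace(0, 1, 50))
    assert np.max(np.abs(refit - arc)) <= 1e-8


def test_collinear_arc_degenerates_to_chord():
    arc = np.column_stack([np.linspace(0, 19, 20), np.linspace(0, 38, 20)])
    seg = fit_segment(arc, degree=5)
    # all control points on the chord; refit curve hugs it
    d = seg.control_points - arc[0]
    chord = arc[-1] - arc[0]
    cross = d[:, 0] * chord[1] - d[:, 1] * chord[0]
    assert np.max(np.abs(cross)) / np.linalg.norm(chord) <= 1e-9
    pts = sample_curve(seg, np.linspace(0, 1, 200))
    dist = np.abs((pts - arc[0]) @ [-chord[1], chord[0]]) / np.linalg.norm(chord)
    assert dist.max() <= 1e-9


def test_quarter_circle_radial_error():
    theta = np.linspace(0, np.pi / 2, 100)
    arc = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
    seg = fit_segment(arc, degree=5)
    dense = sample_curve(seg, np.linspace(0, 1, 2000))
    radial = np.abs(np.linalg.norm(dense, axis=1) - 100.0)
    assert radial.max() <= 0.5


def test_underdetermined_arc_rejected():
    with pytest.raises(UnderdeterminedArcError):
        fit_segment(np.zeros((4, 2)), degree=5)


@pytest.mark.parametrize("degrees", [(3, 5, 7, 9)])
def test_residual_nonincreasing_in_degree(blob_mask, degrees):
    """Nested polynomial spaces: higher degree never fits a fixed arc worse."""
    c = extract_contour(blob_mask[0])
    arcs = split_contour(c, find_extreme_points(c))
    for arc in arcs:
        prev = np.inf
        for n in degrees:
            seg = fit_segment(arc, degree=n)
            fit = sample_curve(seg, np.linspace(0, 1, len(arc)))
            resid = np.mean(np.linalg.norm(fit - arc, axis=1))
            assert resid <= prev + 1e-9
            prev = resid


# ---------------------------------------------------------------- encode

def test_encode_is_40_dimensional(blob_mask):
    code = encode(blob_mask[0])
    assert code.values.shape == (40,)
    assert code.nc == 16


def test_encode_square_high_fidelity(rect_mask):
    code = encode(rect_mask)
    m = rasterize(decode(code), *rect_mask.shape)
    assert mask_iou(m, rect_mask) >= 0.98


def test_encode_translation_equivariance(blob_mask):
    mask = blob_mask[0]
    shifted = np.zeros_like(mask)
    shifted[7:, 10:] = mask[:-7, :-10]
    code = encode(mask)
    code2 = encode(shifted)
    delta = code2.values - code.values
    assert np.max(np.abs(delta[0::2] - 10.0)) <= 1e-6
    assert np.max(np.abs(delta[1::2] - 7.0)) <= 1e-6


def test_encode_rotation_carries_decoded_points(blob_mask):
    """Rotating the mask 90 deg rotates the decoded point multiset
    (extreme-point relabeling permitted)."""
    mask = blob_mask[0]
    h, w = mask.shape
    rot = np.rot90(mask)  # (x, y) -> (y, w - 1 - x)
    pts = decode(encode(mask))
    mapped = np.column_stack([pts[:, 1], (w - 1) - pts[:, 0]])
    pts_rot = decode(encode(rot))
    assert hausdorff(pts_rot, mapped) <= 0.5


# ---------------------------------------------------------------- decode

def test_decode_point_count(blob_mask):
    code = encode(blob_mask[0])
    assert decode(code, samples_per_segment=72).shape == (4 * 71, 2)
    with pytest.raises(ValueError):
        decode(code, samples_per_segment=1)


def test_degenerate_code_rasterizes_empty():
    code = ShapeCode(np.tile([30.0, 40.0], 20))
    contour = decode(code)
    assert np.allclose(contour, [30.0, 40.0])
    assert rasterize(contour, 64, 64).sum() == 0


def test_decode_refinement_consistency(blob_mask):
    code = encode(blob_mask[0])
    coarse = decode(code, samples_per_segment=72)
    fine = decode(code, samples_per_segment=1000)
    spacing = np.linalg.norm(np.diff(np.vstack([coarse, coarse[:1]]), axis=0), axis=1).max()
    assert hausdorff(fine, coarse) <= spacing


# ---------------------------------------------------------------- rasterize

def test_rasterize_square_pixel_count():
    sq = np.array([[10.5, 10.5], [10.5, 50.5], [50.5, 50.5], [50.5, 10.5]])
    assert rasterize(sq, 64, 64).sum() == 40 * 40


def test_rasterize_outside_frame_empty():
    sq = np.array([[100.0, 100.0], [100.0, 120.0], [120.0, 120.0], [120.0, 100.0]])
    assert rasterize(sq, 64, 64).sum() == 0
    with pytest.raises(ValueError):
        rasterize(sq, 0, 64)


def test_rasterize_even_odd_figure_eight():
    bowtie = np.array([[10.2, 10.2], [50.2, 10.2], [10.2, 50.2], [50.2, 50.2]])
    got = rasterize(bowtie, 64, 64)
    expected = brute_force_even_odd(bowtie, 64, 64)
    assert np.array_equal(got, expected)
    # two filled lobes above and below the crossing; outside stays empty
    assert got[17, 30] and got[44, 30] and not got[30, 10]


def test_rasterize_matches_point_in_polygon_oracle(rng):
    poly = np.array([[8.3, 5.1], [30.7, 2.2], [44.9, 20.6], [25.1, 44.8], [4.2, 30.3]])
    assert np.array_equal(rasterize(poly, 48, 48), brute_force_even_odd(poly, 48, 48))


# ---------------------------------------------------------------- round trips

def test_representable_shape_roundtrip(rng):
    """Masks rasterized from valid quintic shapes re-encode with high IoU."""
    from beziermask.codec import PiecewiseShape

    ok = 0
    for seed in range(5):
        g = np.random.default_rng(seed)
        # four extremes of a star-convex-ish layout in a 256 frame
        cx, cy, r = 128.0, 128.0, 70.0 + 10 * g.uniform()
        ext = np.array([[cx, cy - r], [cx - r, cy], [cx, cy + r], [cx + r, cy]])
        segs = []
        for k in range(4):
            a, b = ext[k], ext[(k + 1) % 4]
            interior = np.linspace(a, b, 6)[1:-1] + g.uniform(-12, 12, (4, 2))
            segs.append(BezierSegment(np.vstack([a, interior, b])))
        code = PiecewiseShape(tuple(segs)).to_code()
        mask = rasterize(decode(code, 200), 256, 256)
        if mask.sum() < 4000:
            continue
        code2 = encode(mask)
        iou = mask_iou(rasterize(decode(code2, 200), 256, 256), mask)
        assert iou >= 0.97
        ok += 1
    assert ok >= 3


# ---------------------------------------------------------------- JSON

def test_json_roundtrip_lossless(blob_mask):
    code = encode(blob_mask[0])
    back = ShapeCode.from_json(code.to_json())
    assert np.array_equal(back.values, code.values)
    assert back.degree == code.degree


def test_json_rejects_wrong_length():
    bad = '{"ne": 4, "nc": 16, "degree": 5, "order": "extremes_then_controls", "values": [1.0, 2.0]}'
    with pytest.raises(CodecError):
        ShapeCode.from_json(bad)
    with pytest.raises(CodecError):
        ShapeCode(np.zeros(39))
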