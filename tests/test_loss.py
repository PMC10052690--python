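"""Differentiable decoder linearity, smooth-L1 values, gradients, optimization."""

import numpy as np
import pytest

from beziermask import (
    BDSDConfig,
    BezierSegment,
    LossWeights,
    ShapeCode,
    bdsd_decode,
    encode,
    decode,
    mask_iou,
    optimize_code,
    rasterize,
    smooth_l1,
    total_loss,
)
from beziermask.bezier import evaluate_bernstein
from beziermask.loss import draw_ts, split_samples


def random_code(rng, scale=100.0):
    return ShapeCode(rng.uniform(0, scale, 40))


def test_split_samples_even():
    assert split_samples(72) == (18, 18, 18, 18)
    assert split_samples(7) == (2, 2, 2, 1)


def test_bdsd_endpoint_and_oracle(rng):
    """Decoded points equal per-point Bernstein evaluation of the segments."""
    code = random_code(rng)
    ts = [np.concatenate([[0.0], rng.uniform(0, 1, 17)]) for _ in range(4)]
    pts = bdsd_decode(code, ts)
    assert pts.shape == (72, 2)
    segs = code.segments().segments
    i = 0
    for k in range(4):
        for t in ts[k]:
            oracle = evaluate_bernstein(segs[k], float(t))
            assert np.max(np.abs(pts[i] - oracle)) <= 1e-12
            i += 1
    # t=0 emits the segment's start extreme point
    assert np.allclose(pts[0], code.extreme_points()[0])


def test_bdsd_exact_linearity(rng):
    a, b = random_code(rng), random_code(rng)
    ts = draw_ts(BDSDConfig(seed=0))
    mix = ShapeCode(0.3 * a.values + 0.7 * b.values)
    lhs = bdsd_decode(mix, ts)
    rhs = 0.3 * bdsd_decode(a, ts) + 0.7 * bdsd_decode(b, ts)
    assert np.max(np.abs(lhs - rhs)) <= 1e-10


def test_bdsd_translation(rng):
    code = random_code(rng)
    ts = draw_ts(BDSDConfig(seed=1))
    shifted = code.translated(3.0, -2.0)
    assert np.allclose(bdsd_decode(shifted, ts) - bdsd_decode(code, ts), [3.0, -2.0])


def test_smooth_l1_values():
    assert smooth_l1([0.0], [0.0]) == 0.0
    assert smooth_l1([0.5], [0.0]) == pytest.approx(0.125)
    assert smooth_l1([3.0], [0.0]) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        smooth_l1([1.0, 2.0], [1.0])


def test_total_loss_zero_at_truth(rng):
    code = random_code(rng)
    loss, grad = total_loss(code, code, BDSDConfig(seed=0))
    assert loss == 0.0
    assert np.all(grad == 0.0)


def test_weight_degeneracy(rng):
    pred, truth = random_code(rng), random_code(rng)
    ts = draw_ts(BDSDConfig(seed=2))
    l_ce, _ = total_loss(pred, truth, ts=ts, weights=LossWeights(1.0, 0.0))
    d = pred.values - truth.values
    expected = np.mean(np.where(np.abs(d) < 1, 0.5 * d**2, np.abs(d) - 0.5))
    assert l_ce == pytest.approx(expected, rel=1e-12)
    l_both, _ = total_loss(pred, truth, ts=ts)
    l_match, _ = total_loss(pred, truth, ts=ts, weights=LossWeights(0.0, 1.0))
    assert l_both == pytest.approx(l_ce + l_match, rel=1e-12)


def _near_kink(pred, truth, ts, margin=1e-4):
    d_code = np.abs(pred.values - truth.values)
    from beziermask.loss import decode_matrix

    d_pts = np.abs(decode_matrix(pred.degree, ts) @ (pred.points() - truth.points()))
    return min(np.abs(d_code - 1).min(), np.abs(d_pts - 1).min()) < margin


def test_gradient_matches_finite_differences(rng):
    """Analytic gradient vs central differences away from smooth-L1 kinks."""
    checked = 0
    attempts = 0
    while checked < 25 and attempts < 200:
        attempts += 1
        pred, truth = random_code(rng), random_code(rng)
        ts = draw_ts(BDSDConfig(seed=attempts))
        if _near_kink(pred, truth, ts):
            continue
        _, grad = total_loss(pred, truth, ts=ts)
        eps = 1e-6
        fd = np.zeros(40)
        for i in range(40):
            vp, vm = pred.values.copy(), pred.values.copy()
            vp[i] += eps
            vm[i] -= eps
            fd[i] = (
                total_loss(ShapeCode(vp), truth, ts=ts)[0]
                - total_loss(ShapeCode(vm), truth, ts=ts)[0]
            ) / (2 * eps)
        rel = np.max(np.abs(fd - grad)) / max(np.max(np.abs(fd)), 1e-8)
        assert rel <= 1e-6
        checked += 1
    assert checked == 25


def test_optimize_fixed_point(rng):
    code = random_code(rng)
    res = optimize_code(code, code, BDSDConfig(seed=0), steps=10)
    assert res.final_loss == 0.0
    assert np.allclose(res.code.values, code.values)


def test_optimize_translated_converges(blob_mask):
    mask = blob_mask[0]
    truth = encode(mask)
    res = optimize_code(truth.translated(30, 30), truth, BDSDConfig(seed=1), steps=500)
    truth_mask = rasterize(decode(truth), *mask.shape)
    got = rasterize(decode(res.code), *mask.shape)
    assert mask_iou(got, truth_mask) >= 0.99


def test_optimize_descent_with_fixed_draw(blob_mask):
    truth = encode(blob_mask[0])
    res = optimize_code(
        truth.translated(5, 5), truth, BDSDConfig(seed=3),
        steps=100, step_size=0.5, resample_ts=False,
    )
    assert np.all(np.diff(res.losses) <= 1e-12)
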