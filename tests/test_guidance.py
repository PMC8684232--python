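"""Gaussian click encodings, the weight map, and residual fusion."""

import math

import numpy as np
import pytest

import lesionrefine as lr
from lesionrefine.guidance import GuidanceConfig


def brute_force_guidance(points, radius, shape):
    """Independent double-loop evaluation of the max-composed click kernel."""
    h, w = shape
    out = np.zeros(shape)
    for m in range(h):
        for n in range(w):
            best = 0.0
            for (i, j) in points:
                d2 = (m - i) ** 2 + (n - j) ** 2
                best = max(best, math.exp(-4.0 * d2 / radius**2))
            out[m, n] = best if points else 0.0
    return out


def brute_force_weight(points, radius, shape):
    h, w = shape
    out = np.zeros(shape)
    for m in range(h):
        for n in range(w):
            out[m, n] = sum(
                math.exp(-4.0 * ((m - i) ** 2 + (n - j) ** 2) / radius**2) for (i, j) in points
            )
    return out


def random_clickset(rng, h, w, n_max=5):
    n_pos = int(rng.integers(0, n_max + 1))
    n_neg = int(rng.integers(0, n_max + 1 - n_pos))
    pts = set()
    while len(pts) < n_pos + n_neg:
        pts.add((int(rng.integers(h)), int(rng.integers(w))))
    pts = list(pts)
    return lr.ClickSet(
        [lr.Click(r, c, "positive") for r, c in pts[:n_pos]],
        [lr.Click(r, c, "negative") for r, c in pts[n_pos:]],
    )


class TestGaussianGuidance:
    def test_unit_value_at_click_and_exp_minus_one_at_half_radius(self):
        g = lr.gaussian_guidance([(8, 8)], radius=8.0, shape=(17, 17))
        assert g[8, 8] == 1.0
        assert g[8, 12] == pytest.approx(math.exp(-1.0), abs=1e-12)  # distance R/2

    def test_matches_brute_force_and_max_composition(self, rng):
        for _ in range(30):
            h, w = (int(x) for x in rng.integers(4, 17, size=2))
            pts = [(int(rng.integers(h)), int(rng.integers(w))) for _ in range(5)]
            r = float(rng.uniform(2, 20))
            g = lr.gaussian_guidance(pts, r, (h, w))
            assert np.abs(g - brute_force_guidance(pts, r, (h, w))).max() < 1e-12
            singles = np.stack([lr.gaussian_guidance([p], r, (h, w)) for p in pts])
            assert np.array_equal(g, singles.max(axis=0))

    def test_empty_clicks_give_zero_map(self):
        assert lr.gaussian_guidance([], 10.0, (5, 5)).sum() == 0.0

    def test_radial_monotonic_decay(self):
        g = lr.gaussian_guidance([(10, 10)], 6.0, (21, 21))
        row = g[10, 10:]
        assert np.all(np.diff(row) < 0)

    def test_translation_equivariance(self):
        g0 = lr.gaussian_guidance([(5, 5)], 4.0, (32, 32))
        g1 = lr.gaussian_guidance([(9, 12)], 4.0, (32, 32))
        assert np.allclose(g0[:20, :20], g1[4:24, 7:27], atol=1e-12)

    def test_invalid_radius_and_out_of_bounds_click(self):
        with pytest.raises(ValueError):
            lr.gaussian_guidance([(0, 0)], 0.0, (5, 5))
        with pytest.raises(ValueError):
            lr.gaussian_guidance([(5, 0)], 3.0, (5, 5))


class TestEncodeClicks:
    def test_polarity_channels_and_swap_symmetry(self, rng):
        cs = random_clickset(rng, 16, 16)
        gm = lr.encode_clicks(cs, 5.0, (16, 16))
        swapped = lr.ClickSet(
            [lr.Click(c.row, c.col, "positive") for c in cs.negatives],
            [lr.Click(c.row, c.col, "negative") for c in cs.positives],
        )
        gm2 = lr.encode_clicks(swapped, 5.0, (16, 16))
        assert np.array_equal(gm.g1, gm2.g2) and np.array_equal(gm.g2, gm2.g1)
        if not cs.negatives:
            assert gm.g2.sum() == 0.0


class TestWeightMap:
    def test_coincident_opposite_clicks_sum_to_two(self):
        cs = lr.ClickSet([lr.Click(3, 3, "positive")], [lr.Click(3, 3, "negative")])
        wm = lr.weight_map(cs, 10.0, (8, 8))
        assert wm.w[3, 3] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_sum(self, rng):
        for _ in range(20):
            cs = random_clickset(rng, 16, 16, n_max=4)
            pts = [(c.row, c.col) for c in list(cs.positives) + list(cs.negatives)]
            wm = lr.weight_map(cs, 7.5, (16, 16))
            assert np.abs(wm.w - brute_force_weight(pts, 7.5, (16, 16))).max() < 1e-12
            assert np.all(wm.w <= len(pts) + 1e-12)  # bounded by click count

    def test_sum_dominates_max_at_equal_radius(self, rng):
        cs = random_clickset(rng, 12, 12)
        if len(cs) == 0:
            cs = lr.ClickSet([lr.Click(1, 1, "positive")], [])
        wm = lr.weight_map(cs, 9.0, (12, 12))
        for pool in (cs.positives, cs.negatives):
            if pool:
                g = lr.gaussian_guidance(pool, 9.0, (12, 12))
                assert np.all(wm.w >= g - 1e-12)


class TestFuse:
    def test_zero_weight_or_zero_click_output_is_identity(self, rng):
        b = rng.standard_normal((8, 8))
        c = rng.standard_normal((8, 8))
        assert np.array_equal(lr.fuse(b, c, np.zeros((8, 8))), b)
        assert np.array_equal(lr.fuse(b, np.zeros((8, 8)), rng.uniform(size=(8, 8))), b)

    def test_matches_elementwise_loop(self, rng):
        b, c, w = (rng.standard_normal((8, 8)) for _ in range(3))
        f = lr.fuse(b, c, w)
        for i in range(8):
            for j in range(8):
                assert abs(f[i, j] - (w[i, j] * c[i, j] + b[i, j])) < 1e-12

    def test_linear_in_click_logits(self, rng):
        b, c1, c2, w = (rng.standard_normal((6, 6)) for _ in range(4))
        lhs = lr.fuse(b, 2.0 * c1 + c2, w)
        rhs = lr.fuse(b, c1, w) + w * c1 + lr.fuse(np.zeros_like(b), c2, w)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_far_field_residual_property(self, rng):
        cs = lr.ClickSet([lr.Click(2, 2, "positive")], [])
        wm = lr.weight_map(cs, 3.0, (64, 64))
        b = rng.standard_normal((64, 64))
        c = rng.standard_normal((64, 64))
        f = lr.fuse(b, c, wm)
        far = wm.w < 1e-6
        assert far.any()
        assert np.all(np.abs(f - b)[far] <= 1e-6 * np.abs(c).max())

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            lr.fuse(np.zeros((4, 4)), np.zeros((4, 5)), np.zeros((4, 4)))


def test_guidance_config_scaling():
    g = GuidanceConfig().scaled_for(96)
    assert g.radius == pytest.approx(40.0 * 96 / 256)
    assert g.weight_radius == pytest.approx(120.0 * 96 / 256)
    assert g.weight_radius > g.radius
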