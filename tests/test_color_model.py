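"""Colorimetry, grade calibration and per-pixel classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from kernelpheno import color_model as cm


class TestRgbToLab:
    def test_white_point_exact(self):
        L, a, b = cm.rgb_to_lab(255, 255, 255)
        assert L == pytest.approx(100.0, abs=1e-6)
        assert a == pytest.approx(0.0, abs=1e-6)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_black_exact(self):
        assert cm.rgb_to_lab(0, 0, 0) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_mid_gray_against_closed_form(self):
        # For a gray pixel X/Xn = Y/Yn = Z/Zn = linearized value, so
        # L* = 116 * cbrt(lin) - 16 directly from the standard formulas.
        lin = ((119 / 255 + 0.055) / 1.055) ** 2.4
        expected_L = 116 * np.cbrt(lin) - 16
        L, a, b = cm.rgb_to_lab(119, 119, 119)
        assert L == pytest.approx(expected_L, abs=1e-9)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_skimage_reference(self):
        from skimage.color import rgb2lab

        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (256, 3))
        L, a, b = cm.rgb_to_lab(rgb[:, 0], rgb[:, 1], rgb[:, 2])
        ref = rgb2lab(rgb.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
        # small systematic difference expected: reference whites differ
        assert np.abs(np.stack([L, a, b], axis=1) - ref).max() < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.rgb_to_lab(256, 0, 0)
        with pytest.raises(ValueError):
            cm.rgb_to_lab(-1, 0, 0)

    def test_lab_round_trip_for_kernel_colors(self):
        rng = np.random.default_rng(1)
        L0 = rng.uniform(25, 80, 100)
        a0 = rng.uniform(5, 16, 100)
        b0 = rng.uniform(12, 34, 100)
        r, g, b = cm.lab_to_rgb(L0, a0, b0)
        L1, _, _ = cm.rgb_to_lab(np.round(r), np.round(g), np.round(b))
        assert np.abs(L1 - L0).max() < 0.5  # 8-bit quantization only


class TestDeriveThresholds:
    def test_exact_line_inverts_in_closed_form(self):
        # score = -1 + 0.001 * L  =>  thresholds at 2500, 3500, 4500
        L = np.array([2000.0, 3000.0, 4000.0, 5000.0])
        th = cm.derive_thresholds(L, -1 + 0.001 * L)
        assert th.as_array == pytest.approx([2500.0, 3500.0, 4500.0])

    def test_noisy_recovery_within_2_percent(self):
        rng = np.random.default_rng(12)
        # the calibration set must span the ordinal scale symmetrically,
        # otherwise clipping at the scale ends biases the fitted line
        L = rng.uniform(1800, 5200, 2000)
        score = np.clip(np.round(-1 + 0.001 * L + rng.normal(0, 0.3, 2000)), 1, 4)
        th = cm.derive_thresholds(L, score)
        assert th.as_array == pytest.approx([2500.0, 3500.0, 4500.0], rel=0.02)

    def test_derived_thresholds_equally_spaced(self):
        rng = np.random.default_rng(3)
        L = rng.uniform(30, 90, 500)
        score = np.clip(np.round(L / 20 + rng.normal(0, 0.4, 500)), 1, 4)
        th = cm.derive_thresholds(L, score)
        assert (th.t_l_el - th.t_la_l) - (th.t_la_l - th.t_a_la) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_reference_thresholds_consistent_with_equal_spacing(self):
        th = cm.REFERENCE_THRESHOLDS
        # published to 2 decimals, so spacing agrees to rounding only
        assert abs((th.t_l_el - th.t_la_l) - (th.t_la_l - th.t_a_la)) <= 0.02

    def test_affine_equivariance(self):
        rng = np.random.default_rng(8)
        L = rng.uniform(30, 90, 400)
        score = np.clip(np.round(L / 20 + rng.normal(0, 0.2, 400)), 1, 4)
        th1 = cm.derive_thresholds(L, score)
        th2 = cm.derive_thresholds(657.0 * L, score)
        assert th2.as_array == pytest.approx(657.0 * th1.as_array, rel=1e-9)

    def test_negative_slope_rejected(self):
        L = np.array([10.0, 20, 30, 40])
        with pytest.raises(ValueError, match="slope"):
            cm.derive_thresholds(L, np.array([4, 3, 2, 1]))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            cm.derive_thresholds(np.array([5.0, 5.0]), np.array([1, 2]))


class TestClassifyValue:
    TH = cm.REFERENCE_THRESHOLDS

    @pytest.mark.parametrize(
        "L,expected",
        [
            (5300.0, "extra_light"),
            (4000.0, "light_amber"),
            (3000.0, "amber"),
            (5000.0, "light"),
        ],
    )
    def test_reference_scale_examples(self, L, expected):
        assert cm.classify_value(L, self.TH) == expected

    def test_boundaries_left_closed(self):
        assert cm.classify_value(self.TH.t_la_l, self.TH) == "light"
        assert cm.classify_value(self.TH.t_a_la, self.TH) == "light_amber"
        assert cm.classify_value(self.TH.t_l_el, self.TH) == "extra_light"

    @settings(deadline=None, max_examples=50)
    @given(
        hst.floats(min_value=0, max_value=10000),
        hst.floats(min_value=0, max_value=10000),
    )
    def test_monotone_in_lightness(self, L1, L2):
        lo, hi = sorted([L1, L2])
        order = {c: i for i, c in enumerate(cm.CATEGORIES)}
        assert order[cm.classify_value(lo, self.TH)] <= order[cm.classify_value(hi, self.TH)]


class TestPixelComposition:
    TH = cm.ColorThresholds(40.0, 55.0, 70.0)

    def test_all_extra_light(self):
        comp = cm.pixel_composition(np.full(50, 90.0), self.TH)
        assert comp.as_array == pytest.approx([0, 0, 0, 100])

    def test_even_split(self):
        L = np.array([30.0, 45.0, 60.0, 80.0] * 10)
        comp = cm.pixel_composition(L, self.TH)
        assert comp.as_array == pytest.approx([25, 25, 25, 25])

    def test_matches_per_pixel_loop_and_sums_to_100(self):
        rng = np.random.default_rng(4)
        L = rng.uniform(20, 90, 777)
        comp = cm.pixel_composition(L, self.TH)
        counts = {c: 0 for c in cm.CATEGORIES}
        for v in L:  # brute-force oracle
            counts[cm.classify_value(float(v), self.TH)] += 1
        expected = [counts[c] / len(L) * 100 for c in cm.CATEGORIES]
        assert comp.as_array == pytest.approx(expected, abs=1e-12)
        assert comp.as_array.sum() == pytest.approx(100.0, abs=1e-6)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        L = rng.uniform(20, 90, 101)
        a = cm.pixel_composition(L, self.TH)
        b = cm.pixel_composition(L[::-1].copy(), self.TH)
        assert a == b

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            cm.pixel_composition(np.array([]), self.TH)

    def test_single_band_kernel_median_matches_composition(self):
        rng = np.random.default_rng(6)
        L = rng.uniform(56.0, 69.0, 300)  # entirely inside the "light" band
        comp = cm.pixel_composition(L, self.TH)
        assert comp.pct_light == 100.0
        assert cm.classify_value(float(np.median(L)), self.TH) == "light"


def test_score_category_bijection():
    for i, cat in enumerate(cm.CATEGORIES, start=1):
        assert cm.category_to_score(cat) == i
        assert cm.score_to_category(i) == cat


def test_thresholds_json_round_trip(tmp_path):
    th = cm.ColorThresholds(40.0, 55.0, 70.0, scale_label="native")
    path = tmp_path / "th.json"
    th.to_json(path)
    assert cm.ColorThresholds.from_json(path) == th


def test_unordered_thresholds_rejected():
    with pytest.raises(ValueError):
        cm.ColorThresholds(55.0, 40.0, 70.0)
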