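"""Colorimetry: rim erosion, RGB/gray/HSV/Lab statistics and conversions."""

import numpy as np
import pytest

from berrymorph import (
    compute_color_metrics,
    erode_interior,
    grayscale_from_medians,
    hsv_stats,
    lab_stats,
    rasterize_ellipse_mask,
    rgb_stats,
    srgb_to_cielab,
)


def _patch(color, size=40):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    img[:] = color
    mask = np.ones((size, size), dtype=bool)
    return img, mask


class TestErodeInterior:
    def test_disk_shrinks_by_radius(self):
        disk = rasterize_ellipse_mask(50, 50)
        inner, flag = erode_interior(disk, 10)
        assert flag is True
        assert inner.sum() == pytest.approx(np.pi * 40**2, rel=0.03)

    def test_vanishing_erosion_falls_back(self):
        small = rasterize_ellipse_mask(8, 8)
        out, flag = erode_interior(small, 10)
        assert flag is False
        assert np.array_equal(out, small)

    def test_zero_radius_is_identity(self):
        disk = rasterize_ellipse_mask(20, 20)
        out, flag = erode_interior(disk, 0)
        assert flag is True
        assert np.array_equal(out, disk)


class TestRgbStats:
    def test_uniform_region(self):
        img, mask = _patch((200, 10, 10))
        stats = rgb_stats(img, mask)
        assert (stats["R"]["mean"], stats["G"]["mean"], stats["B"]["mean"]) \
            == (200, 10, 10)
        assert all(stats[ch]["variance"] == 0 for ch in "RGB")

    def test_two_tone_mean_and_lower_median(self):
        img = np.zeros((2, 10, 3), dtype=np.uint8)
        img[0, :, 0] = 100
        img[1, :, 0] = 200
        mask = np.ones((2, 10), dtype=bool)
        stats = rgb_stats(img, mask)
        assert stats["R"]["mean"] == 150
        assert stats["R"]["median"] == 100  # even count -> lower median
        assert stats["R"]["variance"] == pytest.approx(2500)

    def test_shaded_berry_has_positive_variance(self, full_scene):
        _, image, _ = full_scene
        from berrymorph.scene_synthesis import _berry_mask
        spec, _, _ = full_scene
        mask, _ = _berry_mask(spec.berries[0], image.shape[:2])
        assert rgb_stats(image, mask)["R"]["variance"] > 0


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((100, 100, 100), 100.0),    # gray fixed point
        ((255, 0, 0), 76.245),
        ((0, 255, 0), 149.685),
    ])
    def test_rec601_median_luma(self, rgb, expected):
        assert grayscale_from_medians(*rgb) == pytest.approx(expected)

    def test_weights_sum_to_one(self):
        from berrymorph.colorimetry import GRAY_WEIGHTS
        assert sum(GRAY_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-12)


class TestCielab:
    def test_white_black_anchors(self):
        L, a, b = srgb_to_cielab(255, 255, 255)
        assert (L, a, b) == (pytest.approx(100, abs=0.5),
                             pytest.approx(0, abs=0.5),
                             pytest.approx(0, abs=0.5))
        assert srgb_to_cielab(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_pure_red(self):
        L, a, b = srgb_to_cielab(255, 0, 0)
        assert L == pytest.approx(53.2, abs=0.2)
        assert a == pytest.approx(80.1, abs=0.2)
        assert b == pytest.approx(67.2, abs=0.2)

    def test_lightness_monotone_under_brightness_scaling(self):
        base = np.array([180, 60, 50])
        Ls = [srgb_to_cielab(*np.round(s * base).astype(int))[0]
              for s in (1.0, 0.8, 0.5, 0.2)]
        assert all(a > b for a, b in zip(Ls, Ls[1:]))


class TestLabStats:
    def test_uniform_patch_zero_sd(self):
        img, mask = _patch((120, 40, 60))
        stats = lab_stats(img, mask)
        assert all(stats[ch]["sd"] == pytest.approx(0, abs=1e-9)
                   for ch in "Lab")

    def test_two_tone_patch_positive_sd(self):
        img, mask = _patch((120, 40, 60))
        img[:20] = (40, 120, 60)
        assert lab_stats(img, mask)["L"]["sd"] > 0

    def test_red_green_axis_signs(self):
        red_img, mask = _patch((180, 30, 30))
        green_img, _ = _patch((30, 180, 30))
        a_red = lab_stats(red_img, mask)["a"]["mean"]
        a_green = lab_stats(green_img, mask)["a"]["mean"]
        assert a_red > 0 > a_green


class TestHsvStats:
    def test_primary_hues(self):
        red, mask = _patch((255, 0, 0))
        green, _ = _patch((0, 255, 0))
        assert hsv_stats(red, mask)["hue_deg"] == pytest.approx(0, abs=1)
        assert hsv_stats(green, mask)["hue_deg"] == pytest.approx(120, abs=1)

    def test_circular_mean_wraps(self):
        # half hue 350 deg, half hue 10 deg -> circular mean 0, not 180
        img = np.zeros((2, 10, 3), dtype=np.uint8)
        img[0] = (255, 0, 42)   # hue ~350
        img[1] = (255, 42, 0)   # hue ~10
        mask = np.ones((2, 10), dtype=bool)
        hue = hsv_stats(img, mask)["hue_deg"]
        assert min(hue, 360 - hue) < 2


class TestComputeColorMetrics:
    def test_uniform_berry_recovered_exactly_after_erosion(self):
        color = (150, 40, 45)
        img = np.full((120, 120, 3), 255, dtype=np.uint8)
        mask = rasterize_ellipse_mask(45, 35, canvas=(120, 120))
        img[mask] = color
        cm = compute_color_metrics(img, mask, erosion_radius=10)
        assert (cm.red_mean, cm.green_mean, cm.blue_mean) == color
        assert (cm.red_var, cm.green_var, cm.blue_var) == (0, 0, 0)
        assert cm.gray_var == pytest.approx(0, abs=1e-12)
        assert cm.eroded is True
        assert cm.n_pixels_used < int(mask.sum())

    def test_variation_zero_iff_uniform(self):
        img = np.full((120, 120, 3), 255, dtype=np.uint8)
        mask = rasterize_ellipse_mask(45, 35, canvas=(120, 120))
        img[mask] = (150, 40, 45)
        img[60, 60] = (180, 40, 45)  # one off-color interior pixel
        cm = compute_color_metrics(img, mask, erosion_radius=10)
        assert cm.red_var > 0 and cm.gray_var > 0

    def test_erosion_fallback_flagged(self):
        img = np.full((60, 60, 3), 255, dtype=np.uint8)
        mask = rasterize_ellipse_mask(8, 8, canvas=(60, 60))
        img[mask] = (150, 40, 45)
        cm = compute_color_metrics(img, mask, erosion_radius=10)
        assert cm.eroded is False
        assert cm.n_pixels_used == int(mask.sum())
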