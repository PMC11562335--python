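"""Morphometry: orientation, OBB, area/perimeter, solidity, roundness,
width profiles, and the solid-of-revolution volume/surface estimators."""

import numpy as np
import pytest

from berrymorph import (
    EllipsoidReference,
    WidthProfile,
    compute_shape_metrics,
    extract_contour,
    mask_area,
    mask_perimeter,
    oriented_bbox,
    principal_orientation,
    rasterize_ellipse_mask,
    roundness_iso,
    solidity,
    spheroid_reference,
    surface_area_frustums,
    volume_stacked_cylinders,
    width_profile,
)
from berrymorph.morphometry import metrics_to_cm
from berrymorph.scene_synthesis import BerrySpec, _berry_mask


def _angle_dist(a, b):
    """Distance between two axis directions, modulo pi."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def _rect_mask(w=10, h=4):
    m = np.zeros((h + 10, w + 10), dtype=bool)
    m[5:5 + h, 5:5 + w] = True
    return m


class TestPrincipalOrientation:
    def test_axis_aligned_ellipse(self, ellipse_mask):
        assert _angle_dist(principal_orientation(ellipse_mask), 0.0) < 0.01

    @pytest.mark.parametrize("rot", [30, 75, 120])
    def test_rotated_ellipse_recovers_construction_angle(self, rot):
        mask = rasterize_ellipse_mask(100, 50, rotation=rot)
        est = principal_orientation(mask)
        assert _angle_dist(est, np.deg2rad(rot)) < 0.01

    def test_disk_accepts_any_direction_but_measures_isotropically(self, disk_mask):
        # any direction is acceptable for a disk; what matters is that the
        # downstream caliper box is square regardless of the angle returned
        angle = principal_orientation(disk_mask)
        assert 0.0 <= angle < np.pi or angle == pytest.approx(0.0, abs=1e-3)
        length, width, _ = oriented_bbox(disk_mask, angle)
        assert length == pytest.approx(width, rel=0.02)

    def test_tiny_mask_rejected(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2:4] = True
        with pytest.raises(ValueError):
            principal_orientation(m)


class TestOrientedBbox:
    @pytest.mark.parametrize("rot", [0, 30, 145])
    def test_ellipse_caliper_dimensions(self, rot):
        mask = rasterize_ellipse_mask(100, 50, rotation=rot)
        length, width, _ = oriented_bbox(mask, principal_orientation(mask))
        assert length == pytest.approx(200, abs=2)
        assert width == pytest.approx(100, abs=2)

    def test_disk_box_is_square(self):
        mask = rasterize_ellipse_mask(50, 50)
        length, width, _ = oriented_bbox(mask, 0.0)
        assert length == pytest.approx(100, abs=2)
        assert width == pytest.approx(100, abs=2)

    def test_rectangle_pixel_extent_convention(self):
        mask = _rect_mask(10, 4)
        length, width, _ = oriented_bbox(mask, principal_orientation(mask))
        assert (length, width) == (10.0, 4.0)

    def test_length_never_below_width(self):
        # feed the orthogonal direction on purpose; extents must swap
        mask = rasterize_ellipse_mask(100, 50)
        length, width, _ = oriented_bbox(mask, np.pi / 2)
        assert length >= width
        assert length == pytest.approx(200, abs=2)

    def test_corners_enclose_mask(self, ellipse_mask):
        _, _, corners = oriented_bbox(ellipse_mask, 0.0)
        ys, xs = np.nonzero(ellipse_mask)
        assert xs.min() >= corners[:, 0].min() - 1
        assert xs.max() <= corners[:, 0].max() + 1


class TestAreaPerimeterSoliditySmoke:
    def test_square_area_is_pixel_count(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        assert mask_area(m) == 100

    def test_disk_area_matches_analytic(self, disk_mask):
        assert mask_area(disk_mask) == pytest.approx(np.pi * 100**2, rel=0.01)

    def test_notch_strictly_reduces_area(self):
        plain, _ = _berry_mask(BerrySpec((80, 80), 45, 35), (160, 160))
        notched, _ = _berry_mask(BerrySpec((80, 80), 45, 35, notch_depth=20),
                                 (160, 160))
        assert mask_area(notched) < mask_area(plain)

    def test_disk_perimeter(self, disk_mask):
        per = mask_perimeter(extract_contour(disk_mask))
        assert per == pytest.approx(2 * np.pi * 100, rel=0.03)

    def test_convex_ellipse_solidity_near_one(self, ellipse_mask):
        assert solidity(ellipse_mask) >= 0.99

    def test_filled_square_solidity(self, square_mask):
        assert solidity(square_mask) == pytest.approx(1.0, abs=0.01)

    def test_wedge_notch_drops_solidity_below_qc(self):
        spec = BerrySpec((100, 100), 50, 40, notch_depth=0.8 * 40)
        mask, _ = _berry_mask(spec, (200, 200))
        assert solidity(mask) < 0.95


class TestRoundness:
    def test_disk_is_round(self, disk_mask):
        assert roundness_iso(disk_mask) == pytest.approx(1.0, abs=0.03)

    def test_two_to_one_ellipse(self, ellipse_mask):
        assert roundness_iso(ellipse_mask) == pytest.approx(0.5, abs=0.03)

    def test_square_root_half(self, square_mask):
        assert roundness_iso(square_mask) == pytest.approx(1 / np.sqrt(2),
                                                           abs=0.03)

    def test_never_exceeds_one(self, disk_mask, ellipse_mask, square_mask):
        for m in (disk_mask, ellipse_mask, square_mask):
            assert 0 < roundness_iso(m) <= 1.0


class TestWidthProfile:
    def test_disk_profile_shape(self):
        p = width_profile(rasterize_ellipse_mask(50, 50), 0.0)
        assert p.h in (100, 101)
        assert p.widths[p.h // 2] == pytest.approx(101, abs=2)
        assert p.widths[0] < 20  # narrow chord at the pole

    def test_rectangle_profile_exact(self):
        p = width_profile(_rect_mask(10, 4), 0.0)
        assert p.h == 10
        assert set(p.widths) == {4.0}

    def test_rotated_profile_matches_axis_aligned(self):
        p0 = width_profile(rasterize_ellipse_mask(100, 60), 0.0)
        m = rasterize_ellipse_mask(100, 60, rotation=37)
        p1 = width_profile(m, principal_orientation(m))
        assert abs(p0.h - p1.h) <= 2
        n = min(p0.h, p1.h) - 4
        a, b = p0.widths[2:2 + n], p1.widths[2:2 + n]
        assert np.abs(a - b).max() <= 4.0  # slope x registration + quantization
        assert np.abs(a - b).mean() <= 1.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            width_profile(np.zeros((10, 10), dtype=bool), 0.0)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            WidthProfile(angle=0.0, h=3, widths=[0.0, 0.0, 0.0])


class TestVolumeEstimator:
    def test_constant_profile_is_stacked_unit_cylinders(self):
        p = WidthProfile(angle=0.0, h=10, widths=[2.0] * 10)
        assert volume_stacked_cylinders(p) == pytest.approx(10 * np.pi)

    @pytest.mark.parametrize("a,b", [(100, 60), (100, 100), (120, 40)])
    def test_spheroid_volume_convergence(self, a, b):
        # Honest convergence bound for integer-width profiles of masks at
        # this size; see the methods note for the quantization analysis.
        p = width_profile(rasterize_ellipse_mask(a, b), 0.0)
        vol = volume_stacked_cylinders(p)
        ref, _ = spheroid_reference(EllipsoidReference(a, b))
        assert vol == pytest.approx(ref, rel=0.005)

    def test_scaling_law(self):
        small = compute_shape_metrics(rasterize_ellipse_mask(50, 30))
        large = compute_shape_metrics(rasterize_ellipse_mask(100, 60))
        assert large.area == pytest.approx(4 * small.area, rel=0.01)
        assert large.volume == pytest.approx(8 * small.volume, rel=0.01)
        assert large.perimeter == pytest.approx(2 * small.perimeter, rel=0.01)


class TestSurfaceEstimator:
    def test_constant_profile_closed_form(self):
        r, h = 3.0, 12
        p = WidthProfile(angle=0.0, h=h, widths=[2 * r] * h)
        expected = 2 * np.pi * r**2 + 2 * np.pi * r * (h - 1)
        assert surface_area_frustums(p) == pytest.approx(expected)

    def test_sphere_within_printed_bound(self):
        p = width_profile(rasterize_ellipse_mask(100, 100), 0.0)
        assert surface_area_frustums(p) == pytest.approx(4 * np.pi * 100**2,
                                                         rel=0.05)

    def test_prolate_spheroid_within_printed_bound(self):
        p = width_profile(rasterize_ellipse_mask(100, 60), 0.0)
        _, ref = spheroid_reference(EllipsoidReference(100, 60))
        assert surface_area_frustums(p) == pytest.approx(ref, rel=0.05)


class TestSpheroidReference:
    def test_unit_sphere(self):
        vol, surf = spheroid_reference(EllipsoidReference(1, 1))
        assert vol == pytest.approx(4 * np.pi / 3)
        assert surf == pytest.approx(4 * np.pi)

    def test_two_to_one_prolate(self):
        vol, surf = spheroid_reference(EllipsoidReference(2, 1))
        assert vol == pytest.approx(8 * np.pi / 3)
        e = np.sqrt(1 - 1 / 4)
        assert surf == pytest.approx(2 * np.pi * (1 + (2 / e) * np.arcsin(e)))
        assert surf == pytest.approx(21.48, abs=0.01)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            EllipsoidReference(1, 2)


class TestShapeMetricsInvariants:
    @pytest.mark.parametrize("rot", [0, 40, 105])
    def test_length_at_least_width_and_ratios_bounded(self, rot):
        sm = compute_shape_metrics(rasterize_ellipse_mask(80, 55, rotation=rot))
        assert sm.length >= sm.width
        assert 0 < sm.roundness <= 1.0
        assert 0 < sm.solidity <= 1.01
        assert sm.area <= sm.length * sm.width

    def test_metrics_to_cm_dimensional_scaling(self):
        sm = compute_shape_metrics(rasterize_ellipse_mask(100, 60))
        cm = metrics_to_cm(sm, 100.0)
        assert cm.length == pytest.approx(sm.length / 100)
        assert cm.area == pytest.approx(sm.area / 1e4)
        assert cm.volume == pytest.approx(sm.volume / 1e6)
        assert cm.roundness == sm.roundness
        assert cm.solidity == sm.solidity
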