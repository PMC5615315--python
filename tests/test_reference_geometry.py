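"""Plane 1, reference slices and reference axes."""
import math

import numpy as np
import pytest

import tibiaslope as ts
from tibiaslope.contour_extraction import segment_tibia, trace_intensity_contour
from tibiaslope.curvature_landmarks import smooth_contour
from tibiaslope.reference_geometry import (
    build_reference_axis,
    chord_at,
    find_tuberosity_point,
    make_plane1,
    select_reference_slice,
)
from conftest import make_cylinder


class TestTuberosityPoint:
    def test_phantom_apex_recovered_within_one_voxel(self, clean_phantom):
        vol, gt = clean_phantom
        mask = segment_tibia(vol)
        pt = find_tuberosity_point(mask, volume=vol)
        for got, want, sp in zip(pt, gt.tuberosity_apex_mm, vol.spacing):
            assert abs(got - want) <= sp + 1e-9

    def test_cylinder_tie_breaks_to_inferior_slice(self):
        """No tuberosity: the anterior-most wall point ties along z and the
        inferior-most candidate in the band wins."""
        vol, _ = make_cylinder(0.0, radius=15.0, height=80.0)
        mask = segment_tibia(vol)
        pt = find_tuberosity_point(mask, band_mm=(10.0, 40.0), volume=vol)
        assert pt[0] == pytest.approx(15.0, abs=0.5)
        assert pt[1] == pytest.approx(0.0, abs=2.4)
        assert pt[2] == pytest.approx(80.0 - 40.0, abs=0.5)

    def test_translation_equivariance_is_exact(self, clean_phantom):
        vol, _ = clean_phantom
        mask = segment_tibia(vol)
        shifted = ts.ImageVolume(
            vol.grid,
            vol.spacing,
            vol.laterality,
            (vol.origin[0] + 5.0, vol.origin[1], vol.origin[2]),
        )
        mask2 = ts.BinaryMask(mask.grid, mask.spacing, mask.laterality, shifted.origin)
        p1 = find_tuberosity_point(mask, volume=vol)
        p2 = find_tuberosity_point(mask2, volume=shifted)
        assert p2[0] - p1[0] == pytest.approx(5.0, abs=1e-9)
        assert p2[1:] == pytest.approx(p1[1:], abs=1e-9)

    def test_empty_mask_and_short_scan_errors(self):
        empty = ts.BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1), "right")
        with pytest.raises(ts.SegmentationError):
            find_tuberosity_point(empty)
        g = np.zeros((12, 3, 12), bool)
        g[3:9, 1, 3:9] = True  # only 6 mm tall: band [10, 40] is empty
        short = ts.BinaryMask(g, (1.0, 1.0, 1.0), "right")
        with pytest.raises(ts.ReferenceConstructionError):
            find_tuberosity_point(short, contour_source="mask")


class TestPlane1:
    def test_z_passthrough_and_uv_invariance(self):
        assert make_plane1((1.0, 2.0, 42.0)).z0 == 42.0
        assert make_plane1((9.0, -3.0, 42.0)).z0 == make_plane1((0.0, 0.0, 42.0)).z0

    def test_plane_intersects_every_phantom(self, default_phantom, default_mask):
        vol, _ = default_phantom
        pt = find_tuberosity_point(default_mask, volume=vol)
        k0 = default_mask.nearest_index(2, make_plane1(pt).z0)
        assert default_mask.grid[:, :, k0].any()


def _elliptic_cylinder(a=25.0, b=15.0, height=70.0, spacing=(0.5, 2.4, 0.5)):
    from tibiaslope.phantom import rasterize_solid

    xs = np.arange(-a - 5, a + 5.01, spacing[0])
    n_side = int(np.ceil((b + 2.0) / spacing[1]))
    ys = np.arange(-n_side, n_side + 1) * spacing[1]
    zs = np.arange(0.0, height + 0.01, spacing[2])

    def inside(x, y, z):
        return ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (z >= 0) & (z <= height)

    return rasterize_solid(inside, xs, ys, zs, spacing)[0]


class TestReferenceSlice:
    def test_longest_ap_chord_of_elliptic_cylinder(self):
        vol = _elliptic_cylinder(a=25.0, b=15.0)
        mask = segment_tibia(vol)
        pt = find_tuberosity_point(mask, volume=vol)
        idx, line1 = select_reference_slice(mask, make_plane1(pt), "AP", volume=vol)
        # SRS passes through the ellipse centre (y = 0); chord = 2a = 50 mm
        assert abs(mask.axis_coords(1)[idx]) <= 2.4 / 2 + 1e-9
        assert line1.length == pytest.approx(50.0, abs=0.5)

    def test_single_slice_mask(self):
        g = np.zeros((40, 3, 60), bool)
        g[5:35, 1, 5:55] = True
        mask = ts.BinaryMask(g, (1.0, 1.0, 1.0), "right")
        plane1 = make_plane1((0.0, 0.0, 30.0))
        idx, _ = select_reference_slice(mask, plane1, "AP", contour_source="mask")
        assert idx == 1

    def test_equal_chords_tie_break(self):
        """Two slices with identical chords: nearer the cross-section
        centroid wins; exact tie falls to the smaller index."""
        g = np.zeros((40, 9, 60), bool)
        for j in (2, 3, 4, 5, 6):
            half = 15 if j in (2, 6) else 10
            g[20 - half : 20 + half, j, 5:55] = True
        mask = ts.BinaryMask(g, (1.0, 1.0, 1.0), "right")
        idx, _ = select_reference_slice(
            mask, make_plane1((0, 0, 30.0)), "AP", contour_source="mask"
        )
        assert idx == 2

    def test_no_intersection_is_an_error(self):
        g = np.zeros((10, 3, 10), bool)
        g[2:8, 1, 2:5] = True
        mask = ts.BinaryMask(g, (1.0, 1.0, 1.0), "right")
        with pytest.raises(ts.ReferenceConstructionError):
            select_reference_slice(mask, make_plane1((0, 0, 9.0)), "AP", contour_source="mask")


class TestReferenceAxis:
    @staticmethod
    def _axis_for(vol):
        mask = segment_tibia(vol)
        pt = find_tuberosity_point(mask, volume=vol)
        idx, line1 = select_reference_slice(mask, make_plane1(pt), "AP", volume=vol)
        contour = trace_intensity_contour(vol, mask, idx, "sagittal")
        return build_reference_axis(contour, line1), line1, contour

    def test_upright_cylinder_axis_is_vertical(self):
        vol, _ = make_cylinder(0.0)
        axis, _, _ = self._axis_for(vol)
        assert np.allclose(axis.direction, [0.0, 0.0, 1.0], atol=1e-6)

    def test_sheared_cylinder_axis_tilt_recovered(self):
        vol, _ = make_cylinder(5.0)
        axis, _, _ = self._axis_for(vol)
        tilt = math.degrees(math.atan2(axis.direction[0], axis.direction[2]))
        assert tilt == pytest.approx(5.0, abs=0.2)

    def test_line2_is_exactly_offset_below_line1(self):
        vol, _ = make_cylinder(5.0)
        axis, line1, contour = self._axis_for(vol)
        z1 = line1.endpoints[0][2]
        assert axis.origin[2] == pytest.approx(z1)
        # walking 10 mm of height down the axis lands on the midpoint of the
        # bone chord at z1 - 10 of the (smoothed) contour
        step = axis.direction * (10.0 / axis.direction[2])
        mid2 = axis.origin - step
        chord2 = chord_at(smooth_contour(contour, 2.0), z1 - 10.0)
        assert mid2[2] == pytest.approx(z1 - 10.0, abs=1e-12)
        assert mid2[0] == pytest.approx(0.5 * (chord2[0] + chord2[1]), abs=1e-9)

    def test_axis_direction_has_positive_superior_component(self, default_result):
        for axis in default_result.axes.values():
            assert axis.direction[2] > 0

    def test_translation_invariance_of_direction(self):
        vol, _ = make_cylinder(5.0)
        moved = ts.ImageVolume(
            vol.grid, vol.spacing, vol.laterality,
            (vol.origin[0] + 7.0, vol.origin[1], vol.origin[2]),
        )
        a1, _, _ = self._axis_for(vol)
        a2, _, _ = self._axis_for(moved)
        assert np.allclose(a1.direction, a2.direction, atol=1e-6)

    def test_short_slice_raises_helpful_error(self):
        g = np.zeros((30, 3, 30), bool)
        g[5:25, 1, 22:28] = True  # only 6 mm tall below the top
        mask = ts.BinaryMask(g, (1.0, 1.0, 1.0), "right")
        from tibiaslope.contour_extraction import trace_contour
        from tibiaslope.reference_geometry import ReferenceLine

        contour = trace_contour(mask, 1, "sagittal")
        line1 = ReferenceLine(endpoints=((5.0, 1.0, 27.0), (24.0, 1.0, 27.0)), role="line1")
        with pytest.raises(ts.ReferenceConstructionError):
            build_reference_axis(contour, line1, offset_mm=10.0)
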