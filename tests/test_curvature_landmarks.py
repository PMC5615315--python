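"""Curvature operator oracles and plateau/concavity landmark detection."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import tibiaslope as ts
from tibiaslope.contour_extraction import Contour2D
from tibiaslope.curvature_landmarks import smooth_contour


def circle_contour(r, n=400, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour2D(
        np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)]),
        0,
        "sagittal",
    )


def ellipse_contour(a, b, n=800):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour2D(np.column_stack([a * np.cos(t), b * np.sin(t)]), 0, "sagittal")


def rounded_plateau_contour(
    half_width=15.0, height=20.0, corner_r=2.0, dip_depth=0.0, n_arc=24, ds=0.25
):
    """A plateau-slice-like shape: flat bottom, vertical sides, (optionally
    dished) top edge with rounded corners of known apex positions."""
    pts = []
    w, h, r = half_width, height, corner_r

    def edge(p0, p1):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        n = max(2, int(np.linalg.norm(p1 - p0) / ds))
        return p0 + (p1 - p0) * np.linspace(0, 1, n, endpoint=False)[:, None]

    def arc(c, a0, a1):
        t = np.linspace(a0, a1, n_arc, endpoint=False)
        return np.column_stack([c[0] + r * np.cos(t), c[1] + r * np.sin(t)])

    pts.append(edge((-w, 0), (w, 0)))
    pts.append(edge((w, 0), (w, h - r)))
    pts.append(arc((w - r, h - r), 0.0, np.pi / 2))
    if dip_depth > 0:  # parabolic dish across the top edge
        xs = np.arange(w - r, -(w - r), -ds)
        ys = h - dip_depth * (1 - (xs / (w - r)) ** 2)
        pts.append(np.column_stack([xs, ys]))
    else:
        pts.append(edge((w - r, h), (-(w - r), h)))
    pts.append(arc((-(w - r), h - r), np.pi / 2, np.pi))
    pts.append(edge((-w, h - r), (-w, 0)))
    return Contour2D(np.vstack(pts), 0, "sagittal")


CORNER_APEX = lambda w, h, r: (  # noqa: E731 - apex of a rounded 90-degree corner
    w - r + r / np.sqrt(2),
    h - r + r / np.sqrt(2),
)


class TestCurvatureOracles:
    @pytest.mark.parametrize("r", [5.0, 10.0, 20.0])
    def test_circle_curvature_is_inverse_radius(self, r):
        prof = ts.contour_curvature(circle_contour(r), sigma_mm=1.0)
        assert prof.kappa.mean() == pytest.approx(1.0 / r, rel=0.02)
        assert np.all(np.abs(prof.kappa - 1.0 / r) < 0.02 / r + 5e-4)

    def test_straight_side_is_flat(self):
        c = rounded_plateau_contour()
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        # mid-bottom vertex (long straight edge far from corners)
        verts = c.open_vertices
        mid = np.argmin(np.abs(verts[:, 0]) + verts[:, 1])
        assert abs(prof.kappa[mid]) < 0.005

    def test_ellipse_tip_curvature(self):
        prof = ts.contour_curvature(ellipse_contour(20.0, 10.0), sigma_mm=1.0)
        assert prof.kappa.max() == pytest.approx(20.0 / 10.0**2, rel=0.05)

    @pytest.mark.parametrize(
        "contour",
        [circle_contour(10.0), ellipse_contour(20.0, 10.0), rounded_plateau_contour()],
        ids=["circle", "ellipse", "plateau"],
    )
    def test_total_turning_is_2pi(self, contour):
        prof = ts.contour_curvature(contour, sigma_mm=1.0)
        verts = contour.vertices
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        w = 0.5 * (np.r_[seg[-1], seg[:-1]] + seg)
        assert np.sum(prof.kappa[:-1] * w) == pytest.approx(2 * np.pi, rel=0.05)

    def test_too_few_vertices_is_an_error(self):
        c = Contour2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]), 0, "sagittal")
        with pytest.raises(ValueError):
            ts.contour_curvature(c, sigma_mm=1.0)

    @given(st.integers(min_value=0, max_value=50))
    def test_convex_polygon_total_turning(self, seed):
        """Conservation: any smoothed convex closed contour turns by 2*pi.

        Polygon edges are densely subdivided so the vertex-weighted loop
        integral is a faithful quadrature of the turning rate."""
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 2 * np.pi, 12))
        radius = rng.uniform(8.0, 14.0)
        corners = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
        pts = []
        loop = np.vstack([corners, corners[:1]])
        for p0, p1 in zip(loop[:-1], loop[1:]):
            n = max(2, int(np.linalg.norm(p1 - p0) / 0.25))
            pts.append(p0 + (p1 - p0) * np.linspace(0, 1, n, endpoint=False)[:, None])
        c = Contour2D(np.vstack(pts), 0, "sagittal")
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        verts = c.vertices
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        w = 0.5 * (np.r_[seg[-1], seg[:-1]] + seg)
        assert np.sum(prof.kappa[:-1] * w) == pytest.approx(2 * np.pi, rel=0.05)


class TestPlateauNodes:
    def test_nodes_at_rounded_corner_apices(self):
        w, h, r = 15.0, 20.0, 2.0
        c = rounded_plateau_contour(w, h, r)
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        nodes = ts.find_plateau_nodes(c, prof, "sagittal", superior_band_mm=8.0)
        ax, ay = CORNER_APEX(w, h, r)
        assert np.hypot(nodes.node_a[0] - ax, nodes.node_a[1] - ay) < 1.0
        assert np.hypot(nodes.node_b[0] + ax, nodes.node_b[1] - ay) < 1.0

    def test_mirror_symmetric_contour_gives_mirror_nodes(self):
        c = rounded_plateau_contour()
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        nodes = ts.find_plateau_nodes(c, prof, "sagittal", superior_band_mm=8.0)
        seg = np.median(np.linalg.norm(np.diff(c.vertices, axis=0), axis=1))
        assert abs(nodes.node_a[0] + nodes.node_b[0]) <= 2 * seg + 1e-9
        assert abs(nodes.node_a[1] - nodes.node_b[1]) <= 2 * seg + 1e-9

    def test_circle_has_no_distinguished_corner(self):
        c = circle_contour(10.0)
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        with pytest.raises(ts.NodeNotFoundError):
            ts.find_plateau_nodes(c, prof, "sagittal")

    @pytest.mark.parametrize("angle_deg", [2.0, 5.0])
    def test_equivariance_under_rotation_and_translation(self, angle_deg):
        c = rounded_plateau_contour()
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        nodes = ts.find_plateau_nodes(c, prof, "sagittal", superior_band_mm=8.0)
        a = np.radians(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        shift = np.array([3.0, -2.0])
        c2 = Contour2D(c.vertices @ R.T + shift, 0, "sagittal")
        prof2 = ts.contour_curvature(c2, sigma_mm=1.0)
        nodes2 = ts.find_plateau_nodes(c2, prof2, "sagittal", superior_band_mm=8.0)
        seg = np.median(np.linalg.norm(np.diff(c.vertices, axis=0), axis=1))
        for n1, n2 in ((nodes.node_a, nodes2.node_a), (nodes.node_b, nodes2.node_b)):
            moved = R @ np.asarray(n1) + shift
            assert np.linalg.norm(moved - np.asarray(n2)) <= 2 * seg + 1e-9


class TestConcavityNodes:
    @staticmethod
    def _nodes_for(c):
        prof = ts.contour_curvature(c, sigma_mm=1.0)
        return ts.find_plateau_nodes(c, prof, "sagittal", superior_band_mm=8.0)

    def test_dished_slice_depth_recovered(self):
        c = rounded_plateau_contour(dip_depth=2.0)
        conc = ts.concavity_nodes(c, self._nodes_for(c))
        assert len(conc.nodes) > 0
        assert conc.max_depth_mm == pytest.approx(2.0, abs=0.3)

    def test_flat_slice_has_no_concavity(self):
        c = rounded_plateau_contour(dip_depth=0.0)
        conc = ts.concavity_nodes(c, self._nodes_for(c))
        assert len(conc.nodes) == 0

    def test_depth_below_threshold_is_ignored(self):
        c = rounded_plateau_contour(dip_depth=0.05)
        conc = ts.concavity_nodes(c, self._nodes_for(c), depth_min_mm=0.1)
        assert len(conc.nodes) == 0


def test_smooth_contour_preserves_area():
    c = ellipse_contour(20.0, 10.0)
    s = smooth_contour(c, sigma_mm=2.0)
    assert s.signed_area == pytest.approx(c.signed_area, rel=1e-3)
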