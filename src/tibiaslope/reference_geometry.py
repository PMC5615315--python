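"""Construction of plane 1, the reference slices and the reference axes.

The transverse reference plane (plane 1) passes through the most anterior
point of the tibial tuberosity.  The sagittal reference slice (SRS) is the
sagittal slice whose tibia cross-section has the longest anterior-posterior
chord inside plane 1; that chord is line 1.  A parallel chord 10 mm distal
(line 2) is clipped to the bone contour, and the sagittal reference axis
(SRA) joins the midpoints of the two lines.  The coronal constructions
(CRS / CRA) are identical with medial-lateral chords of coronal slices.

Because lines 1 and 2 sit just distal to the plateau, the axis depends only
on the proximal tibia: scan length has no influence on it, unlike
diaphyseal long-axis constructions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour_extraction import (
    Contour2D,
    trace_contour,
    trace_intensity_contour,
)
from .curvature_landmarks import smooth_contour
from .errors import ReferenceConstructionError, SegmentationError
from .image_io import BinaryMask, ImageVolume


@dataclass
class TransversePlane:
    """Transverse plane through the tuberosity point (plane 1)."""

    z0: float


@dataclass
class ReferenceLine:
    """A tibia chord in plane 1 (line 1) or its 10 mm-distal parallel
    (line 2); endpoints are 3D (x, y, z) mm points on the bone boundary."""

    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]
    role: str

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.endpoints[0]) + np.asarray(self.endpoints[1]))

    @property
    def length(self) -> float:
        a, b = (np.asarray(e) for e in self.endpoints)
        return float(np.linalg.norm(b - a))


@dataclass
class ReferenceAxis:
    """SRA or CRA: origin at the midpoint of line 1, unit direction pointing
    proximally (positive superior component)."""

    origin: np.ndarray
    direction: np.ndarray
    plane: str
    reference_slice_index: int

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be unit length")
        if d[2] <= 0:
            raise ValueError("axis direction must point superiorly")
        self.direction = d
        self.origin = np.asarray(self.origin, float)

    def inplane(self) -> np.ndarray:
        """Unit in-slice (u, v) direction of the axis for its plane."""
        if self.plane == "sagittal":
            d = np.array([self.direction[0], self.direction[2]])
        else:
            d = np.array([self.direction[1], self.direction[2]])
        n = np.linalg.norm(d)
        if n == 0:
            raise ReferenceConstructionError("axis has no in-plane component")
        return d / n


def find_tuberosity_point(
    mask: BinaryMask,
    band_mm: tuple[float, float] = (10.0, 40.0),
    volume: ImageVolume | None = None,
    contour_source: str = "intensity",
    level: float | None = None,
    tie_tolerance_mm: float = 0.1,
) -> tuple[float, float, float]:
    """Most anterior bone-boundary point inside the tuberosity search band.

    The boundary is taken from the sub-voxel sagittal contours (intensity
    iso-contours when the source volume is available, the binary 0.5 level
    otherwise).  The band is ``band_mm`` (mm inferior to the most superior
    tibial boundary point) and excludes the anterior plateau rim.  Ties are
    broken by the more inferior z, then by proximity to the bone's
    medial-lateral midline, so the result is fully deterministic.
    """
    if not mask.grid.any():
        raise SegmentationError("empty mask")
    ys = mask.axis_coords(1)
    occupied = np.flatnonzero(mask.grid.any(axis=(0, 2)))
    pts = []  # (u, y, v) per contour vertex
    for j in occupied:
        try:
            if contour_source == "intensity" and volume is not None:
                c = trace_intensity_contour(volume, mask, int(j), "sagittal", level=level)
            else:
                c = trace_contour(mask, int(j), "sagittal")
        except Exception:
            continue
        verts = c.open_vertices
        pts.append(
            np.column_stack([verts[:, 0], np.full(len(verts), ys[j]), verts[:, 1]])
        )
    if not pts:
        raise SegmentationError("no traceable sagittal contour")
    allp = np.concatenate(pts)
    z_top = allp[:, 2].max()
    in_band = (allp[:, 2] >= z_top - band_mm[1]) & (allp[:, 2] <= z_top - band_mm[0])
    if not in_band.any():
        raise ReferenceConstructionError(
            "tuberosity search band is empty; the scan's superior-inferior "
            "extent is too short for the configured band"
        )
    cand = allp[in_band]
    y_mid = float(ys[occupied].mean())
    # "most anterior" is resolved with a sub-voxel tolerance: boundary
    # positions are only reliable to a fraction of a voxel, so candidates
    # within tie_tolerance_mm of the maximum count as tied and the
    # documented tie-breaks (inferior-most z, then most central y) decide
    tied = cand[cand[:, 0] >= cand[:, 0].max() - tie_tolerance_mm]
    order = np.lexsort((np.abs(tied[:, 1] - y_mid), tied[:, 2]))
    i = order[0]
    return float(tied[i, 0]), float(tied[i, 1]), float(tied[i, 2])


def make_plane1(point: tuple[float, float, float]) -> TransversePlane:
    """Transverse plane through the tuberosity point (only z matters)."""
    return TransversePlane(z0=float(point[2]))


def chord_at(contour: Contour2D, v_level: float) -> tuple[float, float] | None:
    """u-extent of a contour's crossings of the horizontal line v=v_level.

    Crossings are linearly interpolated along the polyline, so the chord is
    sub-voxel accurate.  Returns None when the contour does not reach the
    level.
    """
    verts = contour.vertices
    v = verts[:, 1] - v_level
    us = []
    hits = np.flatnonzero(v[:-1] * v[1:] < 0)
    for i in hits:
        t = v[i] / (v[i] - v[i + 1])
        us.append(verts[i, 0] + t * (verts[i + 1, 0] - verts[i, 0]))
    on = np.flatnonzero(v[:-1] == 0)
    us.extend(verts[i, 0] for i in on)
    if len(us) < 2:
        return None
    return float(min(us)), float(max(us))


def _ref_contour(mask, volume, slice_index, plane, contour_source):
    if contour_source == "intensity" and volume is not None:
        return trace_intensity_contour(volume, mask, slice_index, plane)
    return trace_contour(mask, slice_index, plane)


def select_reference_slice(
    mask: BinaryMask,
    plane1: TransversePlane,
    direction: str,
    volume: ImageVolume | None = None,
    contour_source: str = "intensity",
    chord_sigma_mm: float = 2.0,
) -> tuple[int, ReferenceLine]:
    """Slice with the longest tibia chord in plane 1, and that chord.

    ``direction='AP'`` scans sagittal slices for the longest
    anterior-posterior chord (defining the SRS); ``direction='ML'`` scans
    coronal slices for the longest medial-lateral chord (CRS).  Chord ties
    are broken by proximity to the cross-section centroid, then by the
    smaller slice index.
    """
    if direction not in ("AP", "ML"):
        raise ValueError("direction must be 'AP' or 'ML'")
    plane = "sagittal" if direction == "AP" else "coronal"
    axis = 1 if plane == "sagittal" else 0
    k0 = mask.nearest_index(2, plane1.z0)
    section = np.take(mask.grid, k0, axis=2)
    if not section.any():
        raise ReferenceConstructionError("plane 1 does not intersect the mask")
    # centroid of the plane-1 cross-section along the slice axis (for ties)
    occ = section.any(axis=1 - axis)
    coords = mask.axis_coords(axis)[occ]
    centroid = float(coords.mean())

    best = None  # (length, slice_index, (umin, umax))
    for s in np.flatnonzero(np.take(mask.grid, k0, axis=2).any(axis=1 - axis)):
        try:
            contour = _ref_contour(mask, volume, int(s), plane, contour_source)
            if chord_sigma_mm > 0:
                contour = smooth_contour(contour, chord_sigma_mm)
        except Exception:
            continue
        chord = chord_at(contour, plane1.z0)
        if chord is None:
            continue
        length = chord[1] - chord[0]
        cand = (int(s), length, chord)
        if best is None or length > best[1] + 1e-9:
            best = cand
        elif abs(length - best[1]) <= 1e-9:
            c_new = abs(mask.axis_coords(axis)[cand[0]] - centroid)
            c_old = abs(mask.axis_coords(axis)[best[0]] - centroid)
            if c_new < c_old - 1e-12:
                best = cand
    if best is None:
        raise ReferenceConstructionError("no slice intersects the mask at plane 1")
    s, _, (u0, u1) = best
    w = float(mask.axis_coords(axis)[s])
    if plane == "sagittal":
        endpoints = ((u0, w, plane1.z0), (u1, w, plane1.z0))
    else:
        endpoints = ((w, u0, plane1.z0), (w, u1, plane1.z0))
    return s, ReferenceLine(endpoints=endpoints, role="line1")


def build_reference_axis(
    contour: Contour2D,
    line1: ReferenceLine,
    offset_mm: float = 10.0,
    chord_sigma_mm: float = 2.0,
) -> ReferenceAxis:
    """Reference axis from the midpoints of line 1 and the parallel chord
    ``offset_mm`` inferior (line 2), clipped to the bone contour.

    ``contour`` is the reference slice's contour.  Raises when the slice
    does not extend ``offset_mm`` below line 1.
    """
    if offset_mm <= 0:
        raise ValueError("offset_mm must be positive")
    plane = contour.plane
    if chord_sigma_mm > 0:
        contour = smooth_contour(contour, chord_sigma_mm)
    z1 = float(line1.endpoints[0][2])
    z2 = z1 - offset_mm
    chord2 = chord_at(contour, z2)
    if chord2 is None:
        raise ReferenceConstructionError(
            f"reference slice does not reach {offset_mm} mm below line 1; "
            "acquire a longer scan or reduce axis_offset_mm"
        )
    if plane == "sagittal":
        w = float(line1.endpoints[0][1])
        e2 = ((chord2[0], w, z2), (chord2[1], w, z2))
    else:
        w = float(line1.endpoints[0][0])
        e2 = ((w, chord2[0], z2), (w, chord2[1], z2))
    line2 = ReferenceLine(endpoints=e2, role="line2")
    d = line1.midpoint - line2.midpoint
    n = np.linalg.norm(d)
    if n == 0:
        raise ReferenceConstructionError("degenerate reference lines")
    return ReferenceAxis(
        origin=line1.midpoint,
        direction=d / n,
        plane=plane,
        reference_slice_index=contour.slice_index,
    )
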