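"""Signed contour curvature and plateau landmark detection.

Curvature operator
------------------
Each closed contour is resampled to uniform arc length, smoothed with a
periodic Gaussian kernel of physical scale ``sigma_mm`` and rescaled about
its centroid to preserve the enclosed area (plain Gaussian smoothing
systematically shrinks a closed curve, which would bias the curvature of
small structures).  Signed curvature is then

    kappa = (u' v'' - v' u'') / (u'^2 + v'^2)^(3/2)

with periodic central differences, positive where the contour is locally
convex.  The plateau rim nodes (A anterior / B posterior in sagittal
slices, medial / lateral in coronal slices) are the maxima of positive
curvature inside the superior portion of the contour, one per half.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .contour_extraction import Contour2D
from .errors import NodeNotFoundError


@dataclass
class CurvatureProfile:
    """Per-vertex signed curvature (1/mm) aligned with a contour's vertices."""

    kappa: np.ndarray
    sigma_mm: float


@dataclass
class PlateauNodes:
    """Rim nodes of one slice: ``node_a`` is the node with the greater u
    (anterior in sagittal slices, medial in coronal slices)."""

    node_a: tuple[float, float]
    node_b: tuple[float, float]
    slice_index: int
    plane: str
    index_a: int = -1  # vertex indices into the source contour
    index_b: int = -1


@dataclass
class ConcavityNodes:
    """Contour vertices of the articular dish: points of the superior arc
    between the rim nodes that fall below the rim-to-rim line."""

    nodes: np.ndarray  # (n, 2) mm; may be empty
    depths_mm: np.ndarray  # perpendicular drop below the AB line, same length
    slice_index: int
    plane: str

    @property
    def max_depth_mm(self) -> float:
        return float(self.depths_mm.max()) if len(self.depths_mm) else 0.0


def _resample_closed(verts: np.ndarray, ds_target: float = 0.25):
    """Uniform arc-length resampling of a closed polyline (first==last)."""
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    m = max(128, int(np.ceil(total / ds_target)))
    si = np.linspace(0.0, total, m, endpoint=False)
    u = np.interp(si, s, verts[:, 0])
    v = np.interp(si, s, verts[:, 1])
    return np.column_stack([u, v]), si, total


def _periodic_curvature(pts: np.ndarray, ds: float) -> np.ndarray:
    """Turning rate dtheta/ds of a smoothed closed curve, per unit of the
    ORIGINAL arc length it was sampled on.

    This is kappa of the smoothed curve scaled by the local speed |dP/ds|;
    where smoothing leaves the curve unchanged (speed 1) it equals plain
    signed curvature, and its loop integral over the original arc length is
    exactly the total turning 2*pi.
    """
    d1 = (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)) / (2.0 * ds)
    d2 = (np.roll(pts, -1, axis=0) - 2.0 * pts + np.roll(pts, 1, axis=0)) / ds**2
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    speed = np.hypot(d1[:, 0], d1[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(speed > 0, num / np.maximum(speed, 1e-12) ** 2, 0.0)
    return kappa


def smooth_contour(contour: Contour2D, sigma_mm: float = 2.0) -> Contour2D:
    """Arc-length Gaussian smoothing of a closed contour, rescaled about its
    centroid to preserve the enclosed area.

    Used wherever sub-voxel geometry is read off the contour (reference
    chords, curvature): smoothing averages out the residual marching-squares
    wiggle on straight stretches without biasing the enclosed shape.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    pts, _, total = _resample_closed(contour.vertices)
    ds = total / len(pts)
    sm = np.column_stack(
        [
            gaussian_filter1d(pts[:, 0], sigma_mm / ds, mode="wrap"),
            gaussian_filter1d(pts[:, 1], sigma_mm / ds, mode="wrap"),
        ]
    )

    def area(p):
        u, w = p[:, 0], p[:, 1]
        return 0.5 * np.sum(u * np.roll(w, -1) - np.roll(u, -1) * w)

    a0, a1 = abs(area(pts)), abs(area(sm))
    if a1 > 0:
        c = sm.mean(axis=0)
        sm = c + (sm - c) * np.sqrt(a0 / a1)
    return Contour2D(
        np.vstack([sm, sm[:1]]), contour.slice_index, contour.plane
    )


def contour_curvature(contour: Contour2D, sigma_mm: float = 2.0) -> CurvatureProfile:
    """Signed curvature at every contour vertex after Gaussian smoothing.

    Raises on degenerate contours (< 8 vertices).  Curvature is computed on
    an arc-length-uniform, area-preserving smoothed copy of the contour and
    interpolated back onto the original vertices.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if contour.open_vertices.shape[0] < 8:
        raise ValueError("contour must have at least 8 vertices")
    verts = contour.vertices
    flip = contour.signed_area < 0
    pts, si, total = _resample_closed(verts)
    ds = total / len(pts)
    sigma_samples = sigma_mm / ds
    sm = np.column_stack(
        [
            gaussian_filter1d(pts[:, 0], sigma_samples, mode="wrap"),
            gaussian_filter1d(pts[:, 1], sigma_samples, mode="wrap"),
        ]
    )
    # area-preserving rescale about the centroid cancels smoothing shrinkage
    def area(p):
        u, w = p[:, 0], p[:, 1]
        return 0.5 * np.sum(u * np.roll(w, -1) - np.roll(u, -1) * w)

    a0, a1 = abs(area(pts)), abs(area(sm))
    if a1 > 0:
        c = sm.mean(axis=0)
        sm = c + (sm - c) * np.sqrt(a0 / a1)
    kappa_s = _periodic_curvature(sm, ds)
    if flip:
        kappa_s = -kappa_s

    # map back to the original vertices by periodic arc-length interpolation
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s_orig = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    kappa = np.interp(
        s_orig,
        np.concatenate([si, [total]]),
        np.concatenate([kappa_s, [kappa_s[0]]]),
    )
    kappa = np.append(kappa, kappa[0])  # closed: last vertex == first
    return CurvatureProfile(kappa=kappa, sigma_mm=float(sigma_mm))


def _half_peak(kappa: np.ndarray, arc: np.ndarray, idx: np.ndarray, n: int, total: float):
    """Best curvature peak among the selected vertex indices of one half.

    The indices are reordered cyclically (starting after the largest gap
    along the contour) so that a rim corner containing the contour's start
    vertex is not split in two.  Returns (vertex_index, kappa_value) or
    raises when the maximum is flat or ambiguous (two near-equal peaks far
    apart), as on a circular slice with no distinguished corner.
    """
    if len(idx) < 3:
        raise NodeNotFoundError("too few superior-region vertices in this half")
    gaps = np.diff(np.concatenate([idx, [idx[0] + n]]))
    start = (int(np.argmax(gaps)) + 1) % len(idx)
    idx = np.roll(idx, -start)
    k = kappa[idx]
    kmax = float(k.max())
    if kmax <= 0:
        raise NodeNotFoundError("no convex vertex in this half")
    if (kmax - k.min()) < 0.05 * abs(kmax):
        raise NodeNotFoundError("flat curvature maximum (no distinguished corner)")
    # local maxima along the ordered half; sequence endpoints are eligible
    interior = np.flatnonzero((k[1:-1] >= k[:-2]) & (k[1:-1] >= k[2:])) + 1
    ends = [i for i in (0, len(k) - 1) if k[i] >= k[1 if i == 0 else -2]]
    peaks = np.unique(np.concatenate([interior, np.array(ends, dtype=int)])) if (
        len(interior) or ends
    ) else np.array([int(np.argmax(k))])
    order = peaks[np.argsort(k[peaks], kind="stable")[::-1]]
    best = order[0]
    if len(order) > 1:
        second = order[1]
        close = (k[best] - k[second]) < 0.05 * abs(k[best])
        d = abs(arc[idx[best]] - arc[idx[second]])
        far = min(d, total - d) > 5.0
        if close and far:
            raise NodeNotFoundError("ambiguous rim node (two near-equal peaks)")
    return int(idx[best]), float(k[best])


def find_plateau_nodes(
    contour: Contour2D,
    profile: CurvatureProfile,
    plane: str,
    superior_band_mm: float = 25.0,
    kappa_min: float = 0.05,
) -> PlateauNodes:
    """Locate the two plateau rim nodes of one slice.

    The search is restricted to vertices within ``superior_band_mm`` below
    the contour's most superior point (so the distal cortex cannot capture
    the maximum), split at the mid-u of that region; the vertex of maximal
    positive curvature in each half is the rim node.  Slices with a flat or
    ambiguous maximum, or whose best candidate is flatter than
    ``kappa_min``, are rejected so they can be skipped downstream.
    """
    verts = contour.open_vertices
    kappa = profile.kappa[: len(verts)]
    if len(kappa) != len(verts):
        raise ValueError("curvature profile does not match contour")
    v = verts[:, 1]
    v_lo = v.max() - superior_band_mm
    region = np.flatnonzero(v >= v_lo)
    if len(region) < 6:
        raise NodeNotFoundError("superior region too small")
    u = verts[:, 0]
    u_mid = 0.5 * (u[region].min() + u[region].max())
    seg = np.linalg.norm(np.diff(contour.vertices, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]

    half_hi = region[u[region] > u_mid]
    half_lo = region[u[region] <= u_mid]
    if len(half_hi) == 0 or len(half_lo) == 0:
        raise NodeNotFoundError("empty superior half")
    n, total = len(verts), float(np.sum(seg))
    ia, ka = _half_peak(kappa, arc, half_hi, n, total)
    ib, kb = _half_peak(kappa, arc, half_lo, n, total)
    if ka < kappa_min or kb < kappa_min:
        raise NodeNotFoundError("rim curvature below kappa_min")
    # coarse-to-fine: the smoothing scale that makes detection robust also
    # drags the peak toward the more convex flank of the corner; re-localise
    # each node at a finer scale within a window around the coarse peak
    fine_sigma = max(0.6, profile.sigma_mm / 2.5)
    if fine_sigma < profile.sigma_mm:
        fine = contour_curvature(contour, fine_sigma).kappa[: len(verts)]
        window = 1.5 * profile.sigma_mm
        for which, idx0 in (("a", ia), ("b", ib)):
            d = np.abs(arc - arc[idx0])
            near = np.flatnonzero(np.minimum(d, total - d) <= window)
            ref = int(near[np.argmax(fine[near])])
            if which == "a":
                ia = ref
            else:
                ib = ref
    return PlateauNodes(
        node_a=tuple(verts[ia]),
        node_b=tuple(verts[ib]),
        slice_index=contour.slice_index,
        plane=plane,
        index_a=ia,
        index_b=ib,
    )


def concavity_nodes(
    contour: Contour2D,
    nodes: PlateauNodes,
    depth_min_mm: float = 0.1,
) -> ConcavityNodes:
    """Vertices of the articular dish: points on the superior arc between
    the rim nodes lying more than ``depth_min_mm`` below the A-B line.

    An empty result is valid (a flat plateau has no concavity)."""
    verts = contour.open_vertices
    n = len(verts)
    ia, ib = nodes.index_a, nodes.index_b
    if ia < 0 or ib < 0:
        raise ValueError("PlateauNodes must carry contour vertex indices")
    # the two open arcs between A and B; keep the more superior one
    arc1 = np.arange(ia + 1, ib) if ia < ib else np.arange(ia + 1, ib + n) % n
    arc2 = np.setdiff1d(np.arange(n), np.concatenate([arc1, [ia, ib]]))
    if len(arc1) == 0 and len(arc2) == 0:
        sel = np.array([], dtype=int)
    elif len(arc1) == 0:
        sel = arc2
    elif len(arc2) == 0:
        sel = arc1
    else:
        sel = arc1 if verts[arc1, 1].mean() >= verts[arc2, 1].mean() else arc2

    a = np.asarray(nodes.node_a, float)
    b = np.asarray(nodes.node_b, float)
    t = b - a
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("coincident rim nodes")
    t /= norm
    nvec = np.array([t[1], -t[0]])
    if nvec[1] > 0:  # orient the normal inferior (toward -v)
        nvec = -nvec
    depths = (verts[sel] - a) @ nvec
    keep = depths > depth_min_mm
    return ConcavityNodes(
        nodes=verts[sel][keep],
        depths_mm=depths[keep],
        slice_index=contour.slice_index,
        plane=nodes.plane,
    )
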