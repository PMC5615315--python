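"""Signed slope samples, normalized profiles, concavity zones, summaries.

Per slice, the tibial slope is the angle between the rim-to-rim line (A-B)
and the line through node A perpendicular to the reference axis; the slope
is positive when node B falls on the inferior side of that perpendicular.
In sagittal slices node B is the posterior rim, so a posteriorly-inferior
plateau gives positive slope; in coronal slices node B is the lateral rim.

Each slice's distance from the reference slice is normalized to the maximum
extent of the plateau on its own side (medial or lateral of the SRS;
anterior or posterior of the CRS), so profiles from different knees can be
compared on a common [0, 1] abscissa.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .config import MeasureConfig
from .contour_extraction import (
    trace_contour,
    trace_intensity_contour,
)
from .curvature_landmarks import (
    concavity_nodes,
    contour_curvature,
    find_plateau_nodes,
)
from .errors import (
    EmptySliceError,
    NodeNotFoundError,
    TibiaSlopeError,
)
from .image_io import BinaryMask, ImageVolume
from .reference_geometry import (
    ReferenceAxis,
    build_reference_axis,
    find_tuberosity_point,
    make_plane1,
    select_reference_slice,
)
from .contour_extraction import segment_tibia

COMPARTMENTS = ("medial", "lateral", "coronal")


@dataclass
class SlopeSample:
    """One slice's signed slope measurement."""

    slice_index: int
    plane: str
    compartment: str
    normalized_distance: float
    slope_deg: float
    in_concavity_zone: bool
    node_a: tuple[float, float]
    node_b: tuple[float, float]
    has_concavity: bool = False
    side: str = ""


@dataclass
class SlopeProfile:
    """Ordered slope samples of one compartment and plane."""

    compartment: str
    plane: str
    samples: list[SlopeSample]
    max_extent_mm: float


@dataclass
class ConcavityZone:
    """Normalized-distance band of slices whose plateau dips below A-B."""

    compartment: str
    bounds: tuple[float, float]


@dataclass
class CompartmentStats:
    mean_deg: float | None = None
    sd_deg: float | None = None
    n: int = 0
    zone_mean_deg: float | None = None
    zone_sd_deg: float | None = None
    zone_n: int = 0


@dataclass
class SubjectSummary:
    """Per-compartment slope statistics for one subject."""

    compartments: dict[str, CompartmentStats]
    zones: dict[str, ConcavityZone]
    metadata: dict = field(default_factory=dict)

    @property
    def mean_lts(self) -> float | None:
        s = self.compartments.get("lateral")
        return s.mean_deg if s else None

    @property
    def mean_mts(self) -> float | None:
        s = self.compartments.get("medial")
        return s.mean_deg if s else None

    def to_dict(self) -> dict:
        out: dict = {"metadata": dict(self.metadata), "compartments": {}, "zones": {}}
        for name, st in self.compartments.items():
            out["compartments"][name] = {
                "mean_deg": st.mean_deg,
                "sd_deg": st.sd_deg,
                "n": st.n,
                "zone_mean_deg": st.zone_mean_deg,
                "zone_sd_deg": st.zone_sd_deg,
                "zone_n": st.zone_n,
            }
        for name, z in self.zones.items():
            out["zones"][name] = {"lo": z.bounds[0], "hi": z.bounds[1]}
        return out


@dataclass
class MeasurementResult:
    """Everything measured from one subject's volume."""

    profiles: dict[str, SlopeProfile]
    samples: list[SlopeSample]
    zones: dict[str, ConcavityZone]
    axes: dict[str, ReferenceAxis]
    tuberosity_point: tuple[float, float, float]
    skipped: list[tuple[str, int, str]]
    unmeasurable: list[str]


def slope_angle(node_a, node_b, axis) -> float:
    """Signed slope (degrees) of the A-B line against the axis perpendicular.

    Positive when node B lies on the inferior side (along -axis) of the line
    through node A perpendicular to the reference axis; this makes a
    posteriorly (sagittal) or laterally (coronal) inferior plateau positive.
    """
    a = np.asarray(node_a, float)
    b = np.asarray(node_b, float)
    t = b - a
    if np.linalg.norm(t) == 0:
        raise ValueError("coincident nodes")
    d = axis.inplane() if hasattr(axis, "inplane") else np.asarray(axis, float)
    d = d / np.linalg.norm(d)
    comp_axis = float(t @ d)
    comp_perp = float(t @ np.array([d[1], -d[0]]))
    return math.degrees(math.atan2(-comp_axis, abs(comp_perp)))


def normalized_distance(
    slice_index: int,
    reference_slice_index: int,
    slice_spacing_mm: float,
    max_extent_mm: float,
) -> float:
    """|slice - reference| distance over the compartment's maximum extent,
    clamped to [0, 1]."""
    if max_extent_mm <= 0:
        raise ValueError("max_extent_mm must be positive (single-slice plateau?)")
    d = abs(slice_index - reference_slice_index) * slice_spacing_mm / max_extent_mm
    return min(max(d, 0.0), 1.0)


def concavity_zone_bounds(
    samples: Sequence[SlopeSample], compartment: str
) -> ConcavityZone | None:
    """Normalized-distance bounds of the largest contiguous concave run.

    Slices whose plateau contour dips below the rim line form the zone; a
    single intervening non-concave slice does not break a run (gap
    tolerance 1).  Returns None when no slice is concave.
    """
    comp = sorted(
        (s for s in samples if s.compartment == compartment),
        key=lambda s: s.slice_index,
    )
    concave = [s for s in comp if s.has_concavity]
    if not concave:
        return None
    runs: list[list[SlopeSample]] = [[concave[0]]]
    for prev, cur in zip(concave, concave[1:]):
        if cur.slice_index - prev.slice_index <= 2:  # tolerate one-slice gaps
            runs[-1].append(cur)
        else:
            runs.append([cur])
    best = max(runs, key=len)
    lo = min(s.normalized_distance for s in best)
    hi = max(s.normalized_distance for s in best)
    return ConcavityZone(compartment=compartment, bounds=(lo, hi))


def _measure_plane(volume, mask, plane, plane1, config, level, skipped):
    """Run one plane's pass: reference construction then per-slice slopes."""
    direction = "AP" if plane == "sagittal" else "ML"
    ax = 1 if plane == "sagittal" else 0
    ref_idx, line1 = select_reference_slice(
        mask,
        plane1,
        direction,
        volume=volume,
        contour_source=config.contour_source,
        chord_sigma_mm=config.curvature_sigma_mm,
    )
    ref_contour = _contour(volume, mask, ref_idx, plane, config, level)
    axis = build_reference_axis(
        ref_contour,
        line1,
        offset_mm=config.axis_offset_mm,
        chord_sigma_mm=config.curvature_sigma_mm,
    )

    coords = mask.axis_coords(ax)
    occupied = np.flatnonzero(
        mask.grid.any(axis=tuple(i for i in range(3) if i != ax))
    )
    ref_coord = coords[ref_idx]
    extents = {}
    for side_sign, side in (((1), "pos"), ((-1), "neg")):
        d = [
            abs(coords[s] - ref_coord)
            for s in occupied
            if side_sign * (coords[s] - ref_coord) > 0
        ]
        extents[side] = max(d) if d else 0.0

    raw = []
    for s in occupied:
        s = int(s)
        if s == ref_idx:
            continue
        side = "pos" if coords[s] > ref_coord else "neg"
        if extents[side] <= 0:
            continue
        try:
            contour = _contour(volume, mask, s, plane, config, level)
            profile = contour_curvature(contour, config.curvature_sigma_mm)
            nodes = find_plateau_nodes(
                contour,
                profile,
                plane,
                superior_band_mm=config.superior_band_mm,
                kappa_min=config.kappa_min,
            )
            conc = concavity_nodes(
                contour, nodes, depth_min_mm=config.concavity_depth_min_mm
            )
            slope = slope_angle(nodes.node_a, nodes.node_b, axis)
        except (EmptySliceError, NodeNotFoundError, ValueError) as exc:
            skipped.append((plane, s, str(exc)))
            continue
        if plane == "sagittal":
            compartment = "medial" if coords[s] > ref_coord else "lateral"
            side_label = compartment
        else:
            compartment = "coronal"
            side_label = "anterior" if coords[s] > ref_coord else "posterior"
        nd = min(abs(coords[s] - ref_coord) / extents[side], 1.0)
        raw.append(
            SlopeSample(
                slice_index=s,
                plane=plane,
                compartment=compartment,
                normalized_distance=float(nd),
                slope_deg=float(slope),
                in_concavity_zone=False,
                node_a=tuple(map(float, nodes.node_a)),
                node_b=tuple(map(float, nodes.node_b)),
                has_concavity=len(conc.nodes) > 0,
                side=side_label,
            )
        )
    return axis, raw, extents


def _contour(volume, mask, slice_index, plane, config, level):
    if config.contour_source == "intensity" and volume is not None:
        return trace_intensity_contour(volume, mask, slice_index, plane, level=level)
    return trace_contour(mask, slice_index, plane)


def measure_profiles(
    volume: ImageVolume,
    mask: BinaryMask | None = None,
    config: MeasureConfig | None = None,
    planes: Iterable[str] = ("sagittal", "coronal"),
) -> MeasurementResult:
    """Full two-plane measurement of one subject.

    Segments the tibia when no mask is supplied, constructs plane 1 and the
    per-plane reference axes, measures a signed slope on every slice medial
    and lateral of the SRS (sagittal pass) and anterior and posterior of the
    CRS (coronal pass), and derives concavity zones.  Slices without an
    unambiguous pair of rim nodes are skipped and logged.
    """
    config = config or MeasureConfig()
    if mask is None:
        mask = segment_tibia(volume)
    if not mask.grid.any():
        raise TibiaSlopeError("mask is empty")
    if mask.grid.shape != volume.grid.shape:
        raise TibiaSlopeError("mask and volume shapes differ")
    level = None
    if config.contour_source == "intensity":
        if np.ptp(volume.grid) > 0:
            level = float(threshold_otsu(volume.grid))
    tub = find_tuberosity_point(
        mask,
        band_mm=config.tuberosity_band_mm,
        volume=volume,
        contour_source=config.contour_source,
        level=level,
    )
    plane1 = make_plane1(tub)

    skipped: list[tuple[str, int, str]] = []
    axes: dict[str, ReferenceAxis] = {}
    samples: list[SlopeSample] = []
    extents_by_plane = {}
    for plane in planes:
        axis, raw, extents = _measure_plane(
            volume, mask, plane, plane1, config, level, skipped
        )
        axes[plane] = axis
        samples.extend(raw)
        extents_by_plane[plane] = extents

    zones: dict[str, ConcavityZone] = {}
    for compartment in ("medial", "lateral"):
        z = concavity_zone_bounds(samples, compartment)
        if z is not None:
            zones[compartment] = z
            for s in samples:
                if (
                    s.compartment == compartment
                    and z.bounds[0] <= s.normalized_distance <= z.bounds[1]
                ):
                    s.in_concavity_zone = True

    profiles: dict[str, SlopeProfile] = {}
    unmeasurable: list[str] = []
    for compartment in COMPARTMENTS:
        comp = sorted(
            (s for s in samples if s.compartment == compartment),
            key=lambda s: (s.normalized_distance, s.slice_index),
        )
        if len(comp) < 2:
            unmeasurable.append(compartment)
            continue
        if compartment == "coronal":
            ext = max(extents_by_plane.get("coronal", {"pos": 0, "neg": 0}).values())
        else:
            key = "pos" if compartment == "medial" else "neg"
            ext = extents_by_plane.get("sagittal", {}).get(key, 0.0)
        profiles[compartment] = SlopeProfile(
            compartment=compartment,
            plane=comp[0].plane,
            samples=comp,
            max_extent_mm=float(ext),
        )
    return MeasurementResult(
        profiles=profiles,
        samples=samples,
        zones=zones,
        axes=axes,
        tuberosity_point=tub,
        skipped=skipped,
        unmeasurable=unmeasurable,
    )


def _mean_sd(values: Sequence[float]):
    arr = np.asarray(values, float)
    if arr.size == 0:
        return None, None
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def summarize(
    result: MeasurementResult, metadata: dict | None = None
) -> SubjectSummary:
    """Per-compartment mean/SD over all valid slices and over the concavity
    zone (sample SD, n-1 denominator).  Unmeasurable compartments are left
    absent rather than zero."""
    compartments: dict[str, CompartmentStats] = {}
    for name, profile in result.profiles.items():
        slopes = [s.slope_deg for s in profile.samples]
        zone_slopes = [s.slope_deg for s in profile.samples if s.in_concavity_zone]
        mean, sd = _mean_sd(slopes)
        zmean, zsd = _mean_sd(zone_slopes)
        compartments[name] = CompartmentStats(
            mean_deg=mean,
            sd_deg=sd,
            n=len(slopes),
            zone_mean_deg=zmean,
            zone_sd_deg=zsd,
            zone_n=len(zone_slopes),
        )
    return SubjectSummary(
        compartments=compartments,
        zones=dict(result.zones),
        metadata=dict(metadata or {}),
    )


def _lts_mts(entry) -> tuple[float, float]:
    if isinstance(entry, SubjectSummary):
        lts, mts = entry.mean_lts, entry.mean_mts
    else:
        lts, mts = entry
    if lts is None or mts is None:
        raise ValueError("subject lacks a mean LTS or MTS")
    return float(lts), float(mts)


def classify_highlighted_zone(
    summaries: Sequence, mts_max: float = 8.0, lts_max: float = 5.5
) -> float:
    """Fraction of subjects with mean MTS < mts_max and mean LTS < lts_max
    (strict inequalities).

    Accepts SubjectSummary objects or plain ``(mean_lts, mean_mts)`` pairs.
    """
    if not summaries:
        raise ValueError("empty subject list")
    hits = 0
    for entry in summaries:
        lts, mts = _lts_mts(entry)
        if lts < lts_max and mts < mts_max:
            hits += 1
    return hits / len(summaries)


def cohort_correlations(summaries: Sequence[SubjectSummary]) -> dict[str, tuple[float, float]]:
    """Pearson correlations of coronal vs medial and coronal vs lateral
    compartment means across a cohort (requires at least 3 subjects)."""
    from scipy.stats import pearsonr

    rows = []
    for s in summaries:
        cts = s.compartments.get("coronal")
        if cts is None or cts.mean_deg is None:
            continue
        if s.mean_mts is None or s.mean_lts is None:
            continue
        rows.append((cts.mean_deg, s.mean_mts, s.mean_lts))
    if len(rows) < 3:
        raise ValueError("need at least 3 complete subjects for correlations")
    arr = np.asarray(rows)
    r_m = pearsonr(arr[:, 0], arr[:, 1])
    r_l = pearsonr(arr[:, 0], arr[:, 2])
    return {
        "coronal_vs_medial": (float(r_m.statistic), float(r_m.pvalue)),
        "coronal_vs_lateral": (float(r_l.statistic), float(r_l.pvalue)),
    }
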