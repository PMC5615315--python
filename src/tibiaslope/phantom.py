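"""Synthetic proximal-tibia phantoms with analytically known slopes.

The phantom emulates the features the measurement pipeline relies on: a
vertical diaphyseal shaft, a flaring metaphysis widening into an elliptical
plateau, two planar plateau facets with configurable sagittal tilts meeting
at a narrow central ridge, an overall coronal tilt, an anterior tuberosity
ridge (continuing distally like the anterior crest, so the anterior border
is locally vertical where the reference lines are drawn), and an optional
elliptical-cap "dish" depression on either facet.

Voxels are sampled at the scan geometry of the target protocol: 0.5 mm
in-plane, 2.4 mm sagittal slice centres (1.6 mm slices + 0.8 mm gap).  Bone
is intensity 1000 on background 0; boundary voxels carry the linear
partial-volume fraction (estimated by subvoxel sampling) so iso-contours
localise the cortex below voxel resolution, and optional Gaussian noise is
added from a seeded generator.

Ground-truth slopes are the analytic dihedral angles between each facet
plane and the plane perpendicular to the shaft, independent of
voxelisation.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .image_io import ImageVolume, save_volume


@dataclass
class PhantomSpec:
    """Ground-truth geometric parameters of one synthetic tibia.

    Slopes are signed degrees: positive sagittal slopes tilt the facet
    posteriorly-inferiorly, a positive coronal slope tilts the lateral side
    inferiorly.  Dish spans are normalized-distance intervals along the
    facet's medial-lateral extent, measured from the central ridge.
    """

    medial_slope_deg: float = 9.0
    lateral_slope_deg: float = 7.0
    coronal_slope_deg: float = 0.0
    medial_dish_depth_mm: float = 0.0
    medial_dish_span: tuple[float, float] = (0.45, 0.70)
    lateral_dish_depth_mm: float = 0.0
    lateral_dish_span: tuple[float, float] = (0.40, 0.60)
    tuberosity_height_mm: float = 10.0
    tuberosity_z_offset_mm: float = 25.0
    tuberosity_width_mm: float = 6.0
    tuberosity_decay_mm: float = 3.0
    shaft_length_mm: float = 60.0
    shaft_radius_mm: float = 15.0
    flare_length_mm: float = 25.0
    plateau_ap_semi_mm: float = 25.0
    plateau_ml_semi_mm: float = 35.0
    ridge_halfwidth_mm: float = 2.0
    dish_ap_radius_mm: float = 10.0
    spacing: tuple[float, float, float] = (0.5, 2.4, 0.5)
    laterality: str = "right"
    bone_intensity: float = 1000.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("medial_slope_deg", "lateral_slope_deg", "coronal_slope_deg"):
            if abs(getattr(self, name)) >= 45.0:
                raise PhantomSpecError(f"{name} must satisfy |slope| < 45 deg")
        if any(s <= 0 for s in self.spacing):
            raise PhantomSpecError("spacing components must be positive")
        if self.shaft_length_mm < 50.0:
            raise PhantomSpecError("shaft_length_mm must be >= 50 mm")
        for span in (self.medial_dish_span, self.lateral_dish_span):
            if not (0.0 <= span[0] < span[1] <= 1.0):
                raise PhantomSpecError("dish spans must be sub-intervals of [0, 1]")
        if self.tuberosity_z_offset_mm < self.flare_length_mm:
            raise PhantomSpecError(
                "tuberosity_z_offset_mm must be >= flare_length_mm: the crest "
                "must start its superior decay at or below the metaphyseal "
                "flare, otherwise the flare outgrows the crest and the most "
                "anterior point is no longer on the tuberosity"
            )
        if self.laterality not in ("left", "right"):
            raise PhantomSpecError("laterality must be 'left' or 'right'")

    @property
    def z_top_mm(self) -> float:
        return self.shaft_length_mm + self.flare_length_mm

    @property
    def z_apex_mm(self) -> float:
        return self.z_top_mm - self.tuberosity_z_offset_mm


@dataclass
class PhantomGroundTruth:
    """Analytic ground truth accompanying a generated phantom (expressed in
    the canonical anterior-medial-superior frame)."""

    expected_slopes_deg: dict[str, float]
    facet_planes: dict[str, dict[str, float]]
    tuberosity_apex_mm: tuple[float, float, float]
    occupancy: np.ndarray
    z_top_mm: float
    spec: PhantomSpec


def _flare_semiaxes(spec: PhantomSpec, z: np.ndarray):
    s = np.clip(
        (z - (spec.z_top_mm - spec.flare_length_mm)) / spec.flare_length_mm, 0.0, 1.0
    )
    ss = s * s * (3.0 - 2.0 * s)  # smoothstep; zero slope at both ends
    a = spec.shaft_radius_mm + (spec.plateau_ap_semi_mm - spec.shaft_radius_mm) * ss
    b = spec.shaft_radius_mm + (spec.plateau_ml_semi_mm - spec.shaft_radius_mm) * ss
    return a, b


def _surface_z(spec: PhantomSpec, x, y):
    """Top (articular) surface height above each (x, y) column."""
    tan_m = math.tan(math.radians(spec.medial_slope_deg))
    tan_l = math.tan(math.radians(spec.lateral_slope_deg))
    tan_c = math.tan(math.radians(spec.coronal_slope_deg))
    zm = spec.z_top_mm + x * tan_m + y * tan_c
    zl = spec.z_top_mm + x * tan_l + y * tan_c
    w = spec.ridge_halfwidth_mm
    t = np.clip((y + w) / (2.0 * w), 0.0, 1.0)
    z_surf = t * zm + (1.0 - t) * zl
    for depth, span, sign in (
        (spec.medial_dish_depth_mm, spec.medial_dish_span, 1.0),
        (spec.lateral_dish_depth_mm, spec.lateral_dish_span, -1.0),
    ):
        if depth > 0:
            yc = sign * 0.5 * (span[0] + span[1]) * spec.plateau_ml_semi_mm
            ry = 0.5 * (span[1] - span[0]) * spec.plateau_ml_semi_mm
            bowl = 1.0 - (x / spec.dish_ap_radius_mm) ** 2 - ((y - yc) / ry) ** 2
            z_surf = z_surf - depth * np.clip(bowl, 0.0, None)
    return z_surf


def _tuberosity_profile(spec: PhantomSpec, y, z):
    g = np.where(
        z <= spec.z_apex_mm,
        1.0,
        np.exp(-(np.maximum(z - spec.z_apex_mm, 0.0)) / spec.tuberosity_decay_mm),
    )
    w = np.exp(-((y / spec.tuberosity_width_mm) ** 2))
    return spec.tuberosity_height_mm * g * w


def _inside(spec: PhantomSpec, x, y, z):
    a, b = _flare_semiaxes(spec, z)
    yy = np.clip(1.0 - (y / b) ** 2, 0.0, None)
    half_x = a * np.sqrt(yy)
    p = _tuberosity_profile(spec, y, z)
    in_xy = (np.abs(y) <= b) & (x <= half_x + p) & (-x <= half_x)
    return in_xy & (z >= 0.0) & (z <= _surface_z(spec, x, y))


def _grid_coords(spec: PhantomSpec):
    sx, sy, sz = spec.spacing
    A, B, h = spec.plateau_ap_semi_mm, spec.plateau_ml_semi_mm, spec.tuberosity_height_mm
    x_min = -math.ceil((A + 3.0) / sx) * sx
    x_max = math.ceil((A + h + 4.0) / sx) * sx
    xs = np.arange(x_min, x_max + sx / 2, sx)
    n_side = math.ceil((B + 1.0) / sy)
    ys = np.arange(-n_side, n_side + 1) * sy
    max_tan = max(
        abs(math.tan(math.radians(spec.medial_slope_deg))),
        abs(math.tan(math.radians(spec.lateral_slope_deg))),
    )
    z_max = spec.z_top_mm + A * max_tan + B * abs(
        math.tan(math.radians(spec.coronal_slope_deg))
    ) + 2.0
    zs = np.arange(0.0, z_max + sz / 2, sz)
    return xs, ys, zs


def surface_z_max(spec: PhantomSpec) -> float:
    """Most superior point of the articular surface (continuum geometry)."""
    A, B = spec.plateau_ap_semi_mm, spec.plateau_ml_semi_mm
    x = np.linspace(-A, A, 801)[:, None]
    y = np.linspace(-B, B, 801)[None, :]
    inside = (x / A) ** 2 + (y / B) ** 2 <= 1.0
    return float(np.where(inside, _surface_z(spec, x, y), -np.inf).max())


def expected_tuberosity_point(
    spec: PhantomSpec, band_mm: tuple[float, float] = (10.0, 40.0)
) -> tuple[float, float, float]:
    """Analytic most-anterior surface point within the tuberosity search
    band, under the measurement's tie-breaks.

    The crest's anterior face is vertical below its apex, so the maximal
    anterior coordinate ties along the face and the inferior-most candidate
    in the band wins; on the midline the anterior limit is
    ``shaft_radius + tuberosity_height``.
    """
    z_top = surface_z_max(spec)
    z_star = z_top - band_mm[1]
    if z_star > spec.z_apex_mm or z_star < 0:
        raise PhantomSpecError(
            "search band does not land on the crest's vertical face; "
            "adjust band or phantom proportions"
        )
    return (spec.shaft_radius_mm + spec.tuberosity_height_mm, 0.0, z_star)


def rasterize_solid(
    inside,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    spacing: tuple[float, float, float],
    intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    laterality: str = "right",
    subsamples: tuple[int, int, int] = (5, 3, 5),
) -> tuple[ImageVolume, np.ndarray]:
    """Rasterise an ``inside(x, y, z) -> bool`` solid onto a voxel grid.

    Interior voxels get the full intensity; voxels on the boundary carry
    the linear partial-volume fraction estimated by subsampling, so
    iso-contours localise the surface well below voxel resolution.  Returns
    the volume and the voxel-centre occupancy grid.
    """
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    occ = inside(X, Y, Z)
    frac = occ.astype(np.float64)
    boundary = ndimage.binary_dilation(occ) ^ ndimage.binary_erosion(occ)
    bi = np.nonzero(boundary)
    if bi[0].size:
        sx, sy, sz = spacing
        nx, ny, nz = subsamples
        ox = (np.arange(nx) - (nx - 1) / 2) / nx
        oy = (np.arange(ny) - (ny - 1) / 2) / ny
        oz = (np.arange(nz) - (nz - 1) / 2) / nz
        acc = np.zeros(bi[0].size)
        xb, yb, zb = xs[bi[0]], ys[bi[1]], zs[bi[2]]
        for dx in ox:
            for dy in oy:
                for dz in oz:
                    acc += inside(xb + dx * sx, yb + dy * sy, zb + dz * sz)
        frac[bi] = acc / (nx * ny * nz)
    grid = intensity * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd, grid.shape)
    vol = ImageVolume(
        grid, spacing, laterality, (float(xs[0]), float(ys[0]), float(zs[0]))
    )
    return vol, occ


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomGroundTruth]:
    """Rasterise a phantom and return it with its analytic ground truth.

    Deterministic: the same spec (including seed) produces bit-identical
    volumes.
    """
    xs, ys, zs = _grid_coords(spec)
    volume, occ = rasterize_solid(
        lambda x, y, z: _inside(spec, x, y, z),
        xs,
        ys,
        zs,
        spec.spacing,
        intensity=spec.bone_intensity,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        laterality=spec.laterality,
    )

    # the grid is in the canonical anterior-medial-superior frame for either
    # laterality; save_volume mirrors left knees back into subject coords
    tan_c = math.tan(math.radians(spec.coronal_slope_deg))
    facets = {
        "medial": {
            "dz_dx": math.tan(math.radians(spec.medial_slope_deg)),
            "dz_dy": tan_c,
            "z_at_center": spec.z_top_mm,
        },
        "lateral": {
            "dz_dx": math.tan(math.radians(spec.lateral_slope_deg)),
            "dz_dy": tan_c,
            "z_at_center": spec.z_top_mm,
        },
    }
    apex = expected_tuberosity_point(spec)
    gt = PhantomGroundTruth(
        expected_slopes_deg={
            "medial": float(spec.medial_slope_deg),
            "lateral": float(spec.lateral_slope_deg),
            "coronal": float(spec.coronal_slope_deg),
        },
        facet_planes=facets,
        tuberosity_apex_mm=apex,
        occupancy=occ,
        z_top_mm=float(spec.z_top_mm),
        spec=spec,
    )
    return volume, gt


DEFAULT_GRID = {
    "lateral": (0.0, 4.0, 7.0, 12.0),
    "medial": (0.0, 5.0, 9.0, 15.0),
    "coronal": (0.0, 2.0),
}


def grid_specs(
    lateral=DEFAULT_GRID["lateral"],
    medial=DEFAULT_GRID["medial"],
    coronal=DEFAULT_GRID["coronal"],
    seeds=(0, 1, 2),
    **overrides,
) -> list[PhantomSpec]:
    """The validation grid of phantom specs (slopes x seeds)."""
    specs = []
    for lts in lateral:
        for mts in medial:
            for cts in coronal:
                for seed in seeds:
                    specs.append(
                        PhantomSpec(
                            lateral_slope_deg=lts,
                            medial_slope_deg=mts,
                            coronal_slope_deg=cts,
                            seed=seed,
                            **overrides,
                        )
                    )
    return specs


def _gt_payload(gt: PhantomGroundTruth) -> dict:
    spec_d = asdict(gt.spec)
    return {
        "expected_slopes_deg": gt.expected_slopes_deg,
        "facet_planes": gt.facet_planes,
        "tuberosity_apex_mm": list(gt.tuberosity_apex_mm),
        "z_top_mm": gt.z_top_mm,
        "spec": spec_d,
    }


def phantom_suite(out_dir: str | Path, seeds=(0, 1, 2), **grid_kwargs) -> list[Path]:
    """Write the validation phantom grid as NIfTI volumes + JSON ground
    truth (occupancy grids are not serialised; regenerate from the spec)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in grid_specs(seeds=seeds, **grid_kwargs):
        stem = (
            f"phantom_lts{spec.lateral_slope_deg:g}_mts{spec.medial_slope_deg:g}"
            f"_cts{spec.coronal_slope_deg:g}_seed{spec.seed}"
        )
        vol, gt = generate_phantom(spec)
        nii = out / f"{stem}.nii.gz"
        save_volume(vol, nii)
        meta = out / f"{stem}.json"
        with open(meta, "w") as fh:
            json.dump(_gt_payload(gt), fh, indent=2)
        paths.append(nii)
    return paths
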