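"""Reading and writing of MRI volumes, masks and measurement reports.

Internal anatomical frame
-------------------------
Every volume is brought into a single right-handed frame at load time:

* axis 0 (``x``): + anterior
* axis 1 (``y``): + medial
* axis 2 (``z``): + superior

Coordinates are millimetres at voxel centres (0-based indices).  Left knees
are mirrored about the sagittal midplane when loaded, so "medial" and
"lateral" mean the same thing for every subject; the recorded laterality is
used to undo the mirror when a left-knee volume is written back to disk.
Sagittal slices therefore run along axis 1, coronal slices along axis 0 and
transverse (axial) planes along axis 2.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import MetadataError, TibiaSlopeError

AXES = ("anterior", "medial", "superior")

_PLANE_AXIS = {"sagittal": 1, "coronal": 0, "axial": 2}


def plane_axis(plane: str) -> int:
    """Grid axis along which slices of the given plane are stacked."""
    try:
        return _PLANE_AXIS[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}") from None


@dataclass
class ImageVolume:
    """A 3D intensity volume in the canonical anterior-medial-superior frame.

    ``origin`` is the mm coordinate of voxel (0, 0, 0)'s centre, so voxel
    ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    laterality: str
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = AXES

    def __post_init__(self) -> None:
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be positive")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        if tuple(self.orientation) != AXES:
            raise ValueError(f"orientation must be {AXES}")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical mm coordinates of voxel centres along one grid axis."""
        return self.origin[axis] + np.arange(self.grid.shape[axis]) * self.spacing[axis]

    def nearest_index(self, axis: int, coord_mm: float) -> int:
        idx = int(round((coord_mm - self.origin[axis]) / self.spacing[axis]))
        return int(np.clip(idx, 0, self.grid.shape[axis] - 1))


@dataclass
class BinaryMask:
    """A boolean segmentation sharing the geometry of its source volume."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    laterality: str
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = AXES

    def __post_init__(self) -> None:
        if self.grid.dtype != bool:
            self.grid = self.grid.astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be positive")

    axis_coords = ImageVolume.axis_coords
    nearest_index = ImageVolume.nearest_index


def _canonicalize(arr: np.ndarray, affine_ras: np.ndarray, laterality: str):
    """Reorder/flip an array with a RAS affine into the A-M-S frame."""
    ornt = nib.orientations.io_orientation(affine_ras)
    if np.any(np.isnan(ornt)):
        raise MetadataError("image orientation is degenerate (affine not invertible)")
    arr_ras = nib.orientations.apply_orientation(arr, ornt)
    aff_ras = affine_ras @ nib.orientations.inv_ornt_aff(ornt, arr.shape)

    sr, sa, ss = (float(np.linalg.norm(aff_ras[:3, i])) for i in range(3))
    r0, a0, s0 = (float(aff_ras[i, 3]) for i in range(3))
    n_r = arr_ras.shape[0]

    # RAS -> (anterior, subject-left, superior)
    grid = np.flip(np.transpose(arr_ras, (1, 0, 2)), axis=1)
    origin = [a0, -r0 - (n_r - 1) * sr, s0]
    spacing = (sa, sr, ss)

    if laterality == "left":  # mirror so +axis1 is medial for either knee
        grid = np.flip(grid, axis=1)
        origin[1] = -(origin[1] + (grid.shape[1] - 1) * spacing[1])
    return np.ascontiguousarray(grid), spacing, tuple(origin)


def _load_nifti(path: Path, laterality: str) -> ImageVolume:
    img = nib.load(str(path))
    affine = img.affine
    if affine is None:
        raise MetadataError(f"{path}: NIfTI affine is missing")
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    if arr.ndim != 3:
        raise MetadataError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    # nibabel affines are RAS by convention
    grid, spacing, origin = _canonicalize(arr, affine, laterality)
    return ImageVolume(grid, spacing, laterality, origin)


def _load_dicom_series(path: Path, laterality: str) -> ImageVolume:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise MetadataError(f"{path}: no readable DICOM series found")
    reader.SetFileNames(files)
    try:
        img = reader.Execute()
    except RuntimeError as exc:  # pragma: no cover - library message passthrough
        raise MetadataError(f"{path}: failed to read DICOM series: {exc}") from exc
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"{path}: non-positive voxel spacing {spacing}")
    direction = np.asarray(img.GetDirection(), float).reshape(3, 3)
    arr = sitk.GetArrayFromImage(img).astype(np.float64)  # (k, j, i)
    arr = np.transpose(arr, (2, 1, 0))
    affine_lps = np.eye(4)
    affine_lps[:3, :3] = direction @ np.diag(spacing)
    affine_lps[:3, 3] = img.GetOrigin()
    affine_ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine_lps
    grid, spc, origin = _canonicalize(arr, affine_ras, laterality)
    return ImageVolume(grid, spc, laterality, origin)


def load_volume(path: str | Path, laterality: str) -> ImageVolume:
    """Load a NIfTI file or a DICOM series directory into the canonical frame.

    Laterality is a required input: it cannot be inferred reliably from a
    cropped proximal-tibia scan, and it determines the medial/lateral axis
    convention (left knees are mirrored, see module docstring).
    """
    if laterality not in ("left", "right"):
        raise ValueError("laterality must be 'left' or 'right'")
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if p.is_dir():
        return _load_dicom_series(p, laterality)
    return _load_nifti(p, laterality)


def load_mask(path: str | Path, laterality: str) -> BinaryMask:
    """Load a binary NIfTI segmentation into the canonical frame."""
    vol = load_volume(path, laterality)
    return BinaryMask(vol.grid > 0.5, vol.spacing, vol.laterality, vol.origin)


def _als_affine(vol: ImageVolume | BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Grid + RAS affine for writing, undoing the left-knee mirror."""
    grid = vol.grid
    ox, oy, oz = vol.origin
    sx, sy, sz = vol.spacing
    if vol.laterality == "left":
        grid = np.flip(grid, axis=1)
        oy = -(oy + (grid.shape[1] - 1) * sy)
    affine = np.array(
        [
            [0.0, -sy, 0.0, -oy],
            [sx, 0.0, 0.0, ox],
            [0.0, 0.0, sz, oz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return grid, affine


def save_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI in true subject coordinates."""
    grid, affine = _als_affine(vol)
    data = grid.astype(np.uint8) if grid.dtype == bool else grid.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def crop_inferior(vol: ImageVolume, mm: float) -> ImageVolume:
    """Drop the most inferior ``mm`` of the volume (scan-length truncation)."""
    n = int(np.floor(mm / vol.spacing[2]))
    if n <= 0:
        return vol
    if n >= vol.grid.shape[2]:
        raise ValueError("truncation removes the whole volume")
    origin = (vol.origin[0], vol.origin[1], vol.origin[2] + n * vol.spacing[2])
    return replace(vol, grid=np.ascontiguousarray(vol.grid[:, :, n:]), origin=origin)


def write_report(summary, samples: Sequence, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-slice CSV and the JSON summary for one subject.

    Fails before creating any file when the sample list is empty, so a
    failed measurement never leaves a partial report behind.
    """
    import pandas as pd

    if not samples:
        raise TibiaSlopeError("no slope samples to report; refusing to write")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}") from exc

    rows = []
    for s in samples:
        d = asdict(s)
        na, nb = d.pop("node_a"), d.pop("node_b")
        d["node_a_u"], d["node_a_v"] = na
        d["node_b_u"], d["node_b_v"] = nb
        rows.append(d)
    csv_path = out / "slope_samples.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    json_path = out / "summary.json"
    payload = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return {"samples": csv_path, "summary": json_path}
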