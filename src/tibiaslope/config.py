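"""Measurement configuration.

All tunable parameters of the measurement pipeline live here so that a
single YAML file can reproduce a run.  Units are millimetres and degrees
throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class MeasureConfig:
    """Parameters of the slope-measurement pipeline.

    Attributes
    ----------
    tuberosity_band_mm:
        Search band for the tibial tuberosity, expressed as distances
        inferior to the most superior tibial voxel.  The band excludes the
        anterior rim of the plateau (which can protrude further anteriorly
        than the tuberosity on some anatomies) and the distal shaft.
    axis_offset_mm:
        Distance between line 1 (in the transverse reference plane) and the
        parallel line 2 used to construct the reference axis.
    curvature_sigma_mm:
        Arc-length scale of the Gaussian smoothing applied to each contour
        before signed curvature is computed.
    superior_band_mm:
        Vertical extent below each contour's most superior point inside
        which plateau rim nodes are searched.  Keeps the distal cortex (and
        the inferior corners of a cropped field of view) from capturing the
        curvature maximum, while still covering the posterior rim of thin
        peripheral slices; being anchored to the contour top, it is
        invariant to how much shaft the scan includes.
    kappa_min:
        Minimum acceptable rim-node curvature (1/mm); slices whose best
        candidate is flatter than this are skipped.
    concavity_depth_min_mm:
        Minimum drop below the rim-to-rim line for a contour vertex to count
        as part of the articular concavity; suppresses discretisation noise.
    contour_source:
        ``"intensity"`` traces iso-contours of the masked image at the
        automatic threshold (sub-voxel accurate when boundary voxels carry
        partial-volume intensities); ``"mask"`` traces the 0.5 iso-level of
        the binary mask and is used when only a segmentation is available.
    """

    tuberosity_band_mm: tuple[float, float] = (10.0, 40.0)
    axis_offset_mm: float = 10.0
    curvature_sigma_mm: float = 2.0
    superior_band_mm: float = 25.0
    kappa_min: float = 0.05
    concavity_depth_min_mm: float = 0.1
    contour_source: str = "intensity"

    def __post_init__(self) -> None:
        lo, hi = self.tuberosity_band_mm
        if not 0 <= lo < hi:
            raise ValueError("tuberosity_band_mm must satisfy 0 <= lo < hi")
        if self.axis_offset_mm <= 0:
            raise ValueError("axis_offset_mm must be positive")
        if self.curvature_sigma_mm <= 0:
            raise ValueError("curvature_sigma_mm must be positive")
        if self.superior_band_mm <= 0:
            raise ValueError("superior_band_mm must be positive")
        if self.contour_source not in ("intensity", "mask"):
            raise ValueError("contour_source must be 'intensity' or 'mask'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MeasureConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tuberosity_band_mm" in raw:
            raw["tuberosity_band_mm"] = tuple(raw["tuberosity_band_mm"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tuberosity_band_mm"] = list(self.tuberosity_band_mm)
        return d
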