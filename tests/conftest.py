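import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tibiaslope import (
    MeasureConfig,
    PhantomSpec,
    generate_phantom,
    measure_profiles,
    segment_tibia,
)
from tibiaslope.phantom import rasterize_solid

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """One noisy phantom at the scan protocol geometry (LTS 7, MTS 9)."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom for sub-voxel geometry assertions."""
    return generate_phantom(PhantomSpec(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def default_mask(default_phantom):
    vol, _ = default_phantom
    return segment_tibia(vol)


@pytest.fixture(scope="session")
def default_result(default_phantom, default_mask):
    vol, _ = default_phantom
    return measure_profiles(vol, mask=default_mask)


@pytest.fixture(scope="session")
def dished_phantom():
    spec = PhantomSpec(seed=2, lateral_dish_depth_mm=2.0, lateral_dish_span=(0.40, 0.60))
    vol, gt = generate_phantom(spec)
    return vol, gt, measure_profiles(vol)


@pytest.fixture(scope="session")
def config():
    return MeasureConfig()


def make_cylinder(
    shear_deg: float = 0.0,
    radius: float = 15.0,
    height: float = 80.0,
    spacing=(0.5, 2.4, 0.5),
    dome: bool = False,
):
    """Vertical (optionally sheared) cylinder volume; anterior = +x.

    With ``dome=True`` the top is a hemispherical cap, leaving no corner
    anywhere on any slice contour (a fully featureless degenerate bone)."""
    tansh = math.tan(math.radians(shear_deg))
    xs = np.arange(-radius - 15.0, radius + 15.0 + height * tansh, spacing[0])
    n_side = int(np.ceil((radius + 2.0) / spacing[1]))
    ys = np.arange(-n_side, n_side + 1) * spacing[1]
    top = height + (radius if dome else 0.0)
    zs = np.arange(0.0, top + spacing[2] / 2, spacing[2])

    def inside(x, y, z):
        xc = x - z * tansh
        core = (xc**2 + y**2 <= radius**2) & (z >= 0) & (z <= height)
        if dome:
            core = core | (
                (xc**2 + y**2 + (z - height) ** 2 <= radius**2) & (z > height)
            )
        return core

    vol, occ = rasterize_solid(inside, xs, ys, zs, spacing)
    return vol, occ
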