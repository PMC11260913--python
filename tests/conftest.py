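import numpy as np
import pytest

from cheesect.phantom import EyeModel, PhantomSpec
from cheesect.segmentation import BinaryMask
from cheesect.volume_io import DensityVolume

SPACING = (1.25, 1.0, 1.0)  # (dz, dy, dx) mm


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_phantom_spec():
    """A wheel small enough for fast end-to-end runs."""
    def make(n_eyes=5, radius_range=(3.0, 6.0), seed=1, **kwargs):
        return PhantomSpec(
            wheel_radius_mm=40.0,
            wheel_height_mm=40.0,
            eyes=EyeModel(n_eyes=n_eyes, radius_range=radius_range),
            seed=seed,
            **kwargs,
        )
    return make


def digitized_sphere(radius_mm, spacing=SPACING, pad=4):
    """Voxelize a sphere by the center-point rule.

    The center sits on a cell corner (half a voxel off the voxel-center
    lattice in every axis) — the generic position for the center-point rule.
    Lattice-aligned centers produce accidentally symmetric digitizations
    whose shape scores fluctuate non-monotonically with radius.
    """
    dz, dy, dx = spacing
    nz = int(2 * radius_mm / dz) + 2 * pad
    ny = int(2 * radius_mm / dy) + 2 * pad
    nx = int(2 * radius_mm / dx) + 2 * pad
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    cz = (nz - 1) * dz / 2 + dz / 2
    cy = (ny - 1) * dy / 2 + dy / 2
    cx = (nx - 1) * dx / 2 + dx / 2
    return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius_mm**2


def density_volume_with_cavities(cavity_mask, spacing=SPACING,
                                 cheese=1150.0, air=1.2):
    """Uniform cheese block with the given voxels carved out as cavities."""
    rho = np.full(cavity_mask.shape, cheese, dtype=float)
    rho[cavity_mask] = air
    return DensityVolume(rho=rho, spacing=spacing)


def full_wheel_mask(shape, spacing=SPACING):
    """All-true wheel mask (cheese everywhere) for direct labeling tests."""
    return BinaryMask(mask=np.ones(shape, dtype=bool), spacing=spacing)
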