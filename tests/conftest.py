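import numpy as np
import pytest

from cubecyte import (
    BinaryBiovolume,
    IntensityStack,
    VoxelGeometry,
    assign_voxels,
    build_cube_grid,
)
from cubecyte.synthgen import SynthSpec, add_intensity_field, make_colony


@pytest.fixture
def iso1() -> VoxelGeometry:
    """Isotropic 1 µm voxels."""
    return VoxelGeometry(1.0, 1.0, 1.0)


@pytest.fixture
def fine() -> VoxelGeometry:
    """Isotropic 0.25 µm voxels (confocal-like lateral pitch)."""
    return VoxelGeometry(0.25, 0.25, 0.25)


@pytest.fixture
def hemisphere(fine) -> BinaryBiovolume:
    """Surface-attached hemisphere of radius 8 µm at 0.25 µm voxels."""
    spec = SynthSpec(
        shape="hemisphere", volume_voxels=(40, 80, 80), geometry=fine, seed=11,
        radius_um=8.0,
    )
    return make_colony(spec)


@pytest.fixture
def hemisphere_table(hemisphere):
    grid = build_cube_grid(hemisphere, 1.0)
    return grid, assign_voxels(hemisphere, grid)


@pytest.fixture
def two_channel_hemisphere(hemisphere):
    """Hemisphere with a constant channel and a surface-decay reporter."""
    ch1 = add_intensity_field(
        hemisphere, {"type": "constant", "value": 100.0},
        noise={"gaussian_sd": 3.0}, background=5.0, seed=21, channel_name="1",
    )
    ch2 = add_intensity_field(
        hemisphere, {"type": "exp_decay_from_surface", "lam_um": 2.0, "amplitude": 100.0},
        noise={"gaussian_sd": 3.0}, background=5.0, seed=22, channel_name="2",
    )
    return hemisphere, [ch1, ch2]


def random_mask(rng, shape=(6, 12, 12), p=0.4, geometry=None):
    g = geometry or VoxelGeometry(1.0, 1.0, 1.0)
    m = rng.random(shape) < p
    return BinaryBiovolume(m, g)


def random_stack(rng, shape=(4, 16, 16), geometry=None, name="1"):
    g = geometry or VoxelGeometry(1.0, 1.0, 1.0)
    vals = rng.integers(0, 500, size=shape).astype(float)
    return IntensityStack(vals, g, channel_name=name)
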