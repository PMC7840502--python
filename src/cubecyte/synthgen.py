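"""Seeded generator of synthetic biofilm images.

Produces colony-shaped binary ground-truth masks (surface-attached
hemispheres, slabs, wrinkled macrocolony slabs, free-floating spheres),
reporter intensity fields superimposed on them (constant, exponential
decay from the outer surface or the substratum, linear gradients), strain
mixtures, and nested growth series — everything the analysis modules need
for testing and demonstration, without any external image data.

All outputs are pure functions of (spec, seed): a NumPy Generator is
created per call from the explicit seed, never from global state.  Optics
are deliberately idealized: no point-spread function and no deconvolution,
which mirrors the treatment of deconvolution as an external preprocessing
step; shot noise is available as an optional Poisson stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import BinaryBiovolume, ConfigurationError, IntensityStack, VoxelGeometry
from .cube_cytometry import compute_distance_fields

SHAPES = {"hemisphere", "slab", "slab_with_wrinkle", "sphere", "two_strain_blocks",
          "random_mixture"}


@dataclass
class SynthSpec:
    """Specification of a synthetic colony image.

    shape_params (µm):
      hemisphere            radius
      slab                  thickness
      slab_with_wrinkle     thickness, wrinkle_thickness, wrinkle_x (interval)
      sphere                radius (free-floating, centered)
    channels: list of field specs, e.g.
      {"type": "constant", "value": 100}
      {"type": "exp_decay_from_surface", "lam_um": 2.0, "amplitude": 100}
      {"type": "exp_decay_from_substrate", "lam_um": 2.0, "amplitude": 100}
      {"type": "linear_gradient", "axis": "x", "slope": 1.0, "offset": 10.0}
    noise: {"gaussian_sd": float, "poisson": bool}
    """

    shape: str
    volume_voxels: tuple[int, int, int]  # (nz, ny, nx)
    geometry: VoxelGeometry
    seed: int
    radius_um: float = 8.0
    thickness_um: float = 4.0
    wrinkle_thickness_um: float = 8.0
    wrinkle_x_um: tuple[float, float] = (0.0, 0.0)
    channels: list[dict] = field(default_factory=list)
    noise: dict = field(default_factory=dict)
    background: float = 0.0
    substrate_mode: str = "attached"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(f"unknown shape {self.shape!r}; choose from {sorted(SHAPES)}")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")


def _voxel_centers(shape: tuple[int, int, int], g: VoxelGeometry):
    nz, ny, nx = shape
    z = (np.arange(nz) + 0.5) * g.dz
    y = (np.arange(ny) + 0.5) * g.dy
    x = (np.arange(nx) + 0.5) * g.dx
    return z[:, None, None], y[None, :, None], x[None, None, :]


def make_colony(spec: SynthSpec, radius_um: Optional[float] = None) -> BinaryBiovolume:
    """Ground-truth binary mask for the requested colony shape.

    A hemisphere is the set of voxels whose centers lie within radius R of
    the base point (the substratum-plane point under the xy center), with
    z >= 0.  The wrinkled slab is a base slab of thickness h1 plus a ridge
    of thickness h2 > h1 over a stated x interval — the bimodal-thickness
    geometry of wrinkled macrocolonies.
    """
    g = spec.geometry
    shape = spec.volume_voxels
    z, y, x = _voxel_centers(shape, g)
    R = spec.radius_um if radius_um is None else radius_um

    if spec.shape == "hemisphere":
        x0 = shape[2] * g.dx / 2
        y0 = shape[1] * g.dy / 2
        if R > min(x0, y0) or R > shape[0] * g.dz:
            raise ConfigurationError("hemisphere radius exceeds the volume")
        mask = (z**2 + (y - y0) ** 2 + (x - x0) ** 2) <= R**2
    elif spec.shape == "sphere":
        x0 = shape[2] * g.dx / 2
        y0 = shape[1] * g.dy / 2
        z0 = shape[0] * g.dz / 2
        if R > min(x0, y0, z0):
            raise ConfigurationError("sphere radius exceeds the volume")
        mask = ((z - z0) ** 2 + (y - y0) ** 2 + (x - x0) ** 2) <= R**2
    elif spec.shape == "slab":
        if spec.thickness_um > shape[0] * g.dz:
            raise ConfigurationError("slab thicker than the volume")
        mask = np.broadcast_to(z <= spec.thickness_um, shape).copy()
    elif spec.shape == "slab_with_wrinkle":
        h1, h2 = spec.thickness_um, spec.wrinkle_thickness_um
        if h2 <= h1:
            raise ConfigurationError("wrinkle must be thicker than the base slab")
        if h2 > shape[0] * g.dz:
            raise ConfigurationError("wrinkle thicker than the volume")
        in_ridge = (x >= spec.wrinkle_x_um[0]) & (x < spec.wrinkle_x_um[1])
        mask = np.broadcast_to((z <= h1) | (in_ridge & (z <= h2)), shape).copy()
    else:
        raise ConfigurationError(
            f"shape {spec.shape!r} is a strain-mixture pattern; use mix_strains"
        )
    return BinaryBiovolume(mask, g, provenance={"shape": spec.shape, "seed": spec.seed})


def add_intensity_field(
    mask: BinaryBiovolume,
    field_spec: dict,
    noise: Optional[dict] = None,
    background: float = 0.0,
    seed: int = 0,
    channel_name: str = "1",
    substrate_mode: str = "attached",
) -> IntensityStack:
    """Evaluate a reporter field on the foreground, add background and
    seeded noise, and clip at zero.

    ``exp_decay_from_surface`` uses the same anisotropy-aware distance
    transform as the cytometry module, so recovered decay lengths can be
    compared with the imposed ones exactly.
    """
    g = mask.geometry
    m = mask.mask
    ftype = field_spec.get("type")
    vals = np.zeros(m.shape, dtype=float)
    if ftype == "constant":
        vals[m] = field_spec.get("value", 100.0)
    elif ftype == "exp_decay_from_surface":
        lam = field_spec.get("lam_um", 2.0)
        if lam <= 0:
            raise ConfigurationError("decay length must be > 0")
        d = compute_distance_fields(mask, substrate_mode).d_surface
        amp = field_spec.get("amplitude", 100.0)
        vals[m] = amp * np.exp(-d[m] / lam)
    elif ftype == "exp_decay_from_substrate":
        lam = field_spec.get("lam_um", 2.0)
        if lam <= 0:
            raise ConfigurationError("decay length must be > 0")
        amp = field_spec.get("amplitude", 100.0)
        z, _, _ = _voxel_centers(m.shape, g)
        vals[m] = (amp * np.exp(-z / lam) * np.ones(m.shape))[m]
    elif ftype == "linear_gradient":
        axis = {"z": 0, "y": 1, "x": 2}[field_spec.get("axis", "x")]
        coord = _voxel_centers(m.shape, g)[axis] * np.ones(m.shape)
        vals[m] = field_spec.get("offset", 0.0) + field_spec.get("slope", 1.0) * coord[m]
    else:
        raise ConfigurationError(f"unknown field type {ftype!r}")

    vals = vals + background
    noise = noise or {}
    rng = np.random.default_rng(seed)
    if noise.get("poisson"):
        vals = rng.poisson(np.maximum(vals, 0)).astype(float)
    sd = noise.get("gaussian_sd", 0.0)
    if sd > 0:
        vals = vals + rng.normal(0.0, sd, size=vals.shape)
    vals = np.clip(vals, 0.0, None)
    return IntensityStack(vals, g, channel_name=channel_name)


def mix_strains(
    mask: BinaryBiovolume,
    fractions: Sequence[float],
    cluster_edge_um: float,
    seed: int,
    bright: float = 200.0,
    dim: float = 10.0,
) -> list[IntensityStack]:
    """Partition the biovolume into cubic patches and assign each patch to a
    strain with the given probabilities; each strain's channel is bright on
    its own patches and dim elsewhere in the mask.

    Emulates mixed-strain colonies whose clonal patch size is set by the
    founder density and growth, here controlled by ``cluster_edge_um``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ConfigurationError("fractions must be non-negative and sum to 1")
    g = mask.geometry
    if cluster_edge_um < max(g.dx, g.dy, g.dz):
        raise ConfigurationError("cluster_edge_um must be at least one voxel pitch")
    span = [max(1, round(cluster_edge_um / p)) for p in g.spacing_zyx]
    nz, ny, nx = mask.shape
    kz = np.arange(nz) // span[0]
    ky = np.arange(ny) // span[1]
    kx = np.arange(nx) // span[2]
    npz, npy, npx = kz.max() + 1, ky.max() + 1, kx.max() + 1
    rng = np.random.default_rng(seed)
    patch_strain = rng.choice(len(fractions), size=npz * npy * npx, p=fractions)
    patch_id = (
        kz[:, None, None] * (npy * npx) + ky[None, :, None] * npx + kx[None, None, :]
    )
    strain_of_voxel = patch_strain[patch_id]
    stacks = []
    for s in range(len(fractions)):
        vals = np.zeros(mask.shape, dtype=float)
        vals[mask.mask] = np.where(strain_of_voxel[mask.mask] == s, bright, dim)
        stacks.append(IntensityStack(vals, g, channel_name=str(s + 1)))
    return stacks


def grow_series(
    spec: SynthSpec,
    n_frames: int,
    growth_rule: Callable[[int], float],
    drift_per_frame: tuple[int, int] = (0, 0),
) -> list[BinaryBiovolume]:
    """Nested growth series: frame t is the colony at size growth_rule(t),
    optionally translated by a cumulative integer xy drift.

    With zero drift each frame strictly contains its predecessor, which is
    the geometry assumed by the positional tracking scheme.
    """
    if n_frames < 2:
        raise ConfigurationError("a series needs at least 2 frames")
    sizes = [float(growth_rule(t)) for t in range(n_frames)]
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise ConfigurationError("growth rule must be monotone non-decreasing")
    frames = []
    for t, size in enumerate(sizes):
        if spec.shape in {"hemisphere", "sphere"}:
            m = make_colony(spec, radius_um=size)
        elif spec.shape == "slab":
            sub = SynthSpec(
                shape="slab",
                volume_voxels=spec.volume_voxels,
                geometry=spec.geometry,
                seed=spec.seed,
                thickness_um=size,
            )
            m = make_colony(sub)
        else:
            raise ConfigurationError(f"growth series unsupported for {spec.shape!r}")
        if drift_per_frame != (0, 0):
            from .timeseries import shift_volume

            sx, sy = drift_per_frame
            shifted = shift_volume(m.mask, (sx * t, sy * t))
            m = BinaryBiovolume(shifted, spec.geometry, provenance=m.provenance)
        frames.append(m)
    return frames
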