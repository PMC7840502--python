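"""Dissection of the binary biovolume into a cubical grid of pseudocells.

The cube edge length is specified in µm and converted to voxels per axis by
rounding, so cubes are physically comparable across datasets with different
voxel pitches.  Cube regions are half-open voxel index ranges
``[i*s, min((i+1)*s, n))``; edge cubes may therefore be truncated, and are
kept with a ``truncated`` flag (their fill fraction uses the truncated
region size as denominator, avoiding a spurious low-density rim).

2D images (degenerate z) are dissected into squares: the z span is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinaryBiovolume, ConfigurationError, DimensionError, VoxelGeometry

#: Columns identifying a record rather than describing its biomass.
INDEX_COLUMNS = ["frame", "cube_id", "i", "j", "k"]
BOOKKEEPING_COLUMNS = ["region_voxels", "fg_voxels", "truncated"]


@dataclass(frozen=True)
class CubeGrid:
    """Cubical grid over a voxel volume.

    span   voxels per cube along (x, y, z): round(edge_um / pitch), each >= 1
    counts cubes along (x, y, z): ceil(voxels / span)
    """

    edge_um: float
    span: tuple[int, int, int]  # (sx, sy, sz)
    counts: tuple[int, int, int]  # (nx, ny, nz)
    voxel_shape: tuple[int, int, int]  # (nz_vox, ny_vox, nx_vox)
    geometry: VoxelGeometry

    @property
    def n_cubes(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    @property
    def edge_lengths_um(self) -> tuple[float, float, float]:
        """Realized physical cube edge along (x, y, z) after voxel rounding."""
        sx, sy, sz = self.span
        g = self.geometry
        return (sx * g.dx, sy * g.dy, sz * g.dz)

    def linear_id(self, i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Linear cube index with x fastest (VTK cell ordering)."""
        nx, ny, _ = self.counts
        return i + nx * (j + ny * k)

    def grid_indices(self, cube_id: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, _ = self.counts
        i = cube_id % nx
        j = (cube_id // nx) % ny
        k = cube_id // (nx * ny)
        return i, j, k

    def cube_id_map(self) -> np.ndarray:
        """Array of shape voxel_shape mapping every voxel to its cube_id."""
        nz_vox, ny_vox, nx_vox = self.voxel_shape
        sx, sy, sz = self.span
        i = np.arange(nx_vox) // sx
        j = np.arange(ny_vox) // sy
        k = np.arange(nz_vox) // sz
        return self.linear_id(
            i[np.newaxis, np.newaxis, :],
            j[np.newaxis, :, np.newaxis],
            k[:, np.newaxis, np.newaxis],
        )


class CubeTable:
    """One row per occupied cube (or imported object) per frame.

    Wraps a pandas DataFrame plus the grid and a registry of parameter
    columns (the cytometry quantities, as opposed to index/bookkeeping
    columns).  ``assignment`` maps every voxel to its row index (-1 for
    voxels that belong to no record), which lets all voxel-level cytometry
    run identically for grid cubes and imported labeled objects.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        grid: CubeGrid | None,
        geometry: VoxelGeometry,
        assignment: np.ndarray | None = None,
        frame: int = 0,
    ):
        self.df = df.reset_index(drop=True)
        self.grid = grid
        self.geometry = geometry
        self.assignment = assignment
        self.frame = frame
        self.parameters: list[str] = [
            c for c in df.columns if c not in INDEX_COLUMNS + BOOKKEEPING_COLUMNS
        ]
        self.channels: list[str] = []

    def __len__(self) -> int:
        return len(self.df)

    def add_parameter(self, name: str, values) -> None:
        if name in self.df.columns:
            raise ConfigurationError(f"parameter {name!r} already exists")
        self.df[name] = np.asarray(values, dtype=float)
        self.parameters.append(name)

    def copy_with(self, df: pd.DataFrame) -> "CubeTable":
        out = CubeTable(df, self.grid, self.geometry, assignment=None, frame=self.frame)
        out.parameters = [p for p in self.parameters if p in df.columns]
        out.channels = list(self.channels)
        return out


def build_cube_grid(mask: BinaryBiovolume, edge_um: float) -> CubeGrid:
    """Build the cube grid for a mask; squares (sz=1) for 2D inputs."""
    g = mask.geometry
    nz_vox, ny_vox, nx_vox = mask.shape
    pitches = [g.dx, g.dy, g.dz]
    relevant = [g.dx, g.dy] + ([g.dz] if nz_vox > 1 else [])
    if edge_um < max(relevant):
        raise ConfigurationError(
            f"cube edge {edge_um} µm is smaller than one voxel "
            f"(max pitch {max(relevant)} µm)"
        )
    span = tuple(max(1, round(edge_um / p)) for p in pitches)
    sx, sy, sz = span
    if nz_vox == 1:
        sz = 1
    counts = (
        int(np.ceil(nx_vox / sx)),
        int(np.ceil(ny_vox / sy)),
        int(np.ceil(nz_vox / sz)),
    )
    return CubeGrid(edge_um, (sx, sy, sz), counts, mask.shape, g)


def assign_voxels(mask: BinaryBiovolume, grid: CubeGrid, frame: int = 0) -> CubeTable:
    """Partition foreground voxels over the grid; one record per occupied cube.

    Conservation is exact: the fg_voxels column sums to the mask's total
    foreground count, since every voxel belongs to exactly one cube.
    """
    if grid.voxel_shape != mask.shape:
        raise DimensionError("grid was built for a different mask shape")
    cube_ids = grid.cube_id_map()
    n_cubes = grid.n_cubes
    fg_counts = np.bincount(cube_ids[mask.mask], minlength=n_cubes)

    nz_vox, ny_vox, nx_vox = mask.shape
    sx, sy, sz = grid.span
    nx, ny, nz = grid.counts
    # Per-axis region extents, truncated at the volume boundary.
    ext_x = np.minimum((np.arange(nx) + 1) * sx, nx_vox) - np.arange(nx) * sx
    ext_y = np.minimum((np.arange(ny) + 1) * sy, ny_vox) - np.arange(ny) * sy
    ext_z = np.minimum((np.arange(nz) + 1) * sz, nz_vox) - np.arange(nz) * sz

    occupied = np.flatnonzero(fg_counts)
    if occupied.size == 0:
        warnings.warn("empty mask: cube table has no records", stacklevel=2)
    i, j, k = grid.grid_indices(occupied)
    region = ext_x[i] * ext_y[j] * ext_z[k]
    truncated = (ext_x[i] < sx) | (ext_y[j] < sy) | (ext_z[k] < min(sz, nz_vox))

    df = pd.DataFrame(
        {
            "frame": frame,
            "cube_id": occupied,
            "i": i,
            "j": j,
            "k": k,
            "region_voxels": region,
            "fg_voxels": fg_counts[occupied],
            "truncated": truncated,
        }
    )
    # Voxel -> row index map for downstream per-record statistics.
    row_of_cube = np.full(n_cubes, -1, dtype=np.int64)
    row_of_cube[occupied] = np.arange(occupied.size)
    assignment = np.where(mask.mask, row_of_cube[cube_ids], -1)
    return CubeTable(df, grid, mask.geometry, assignment=assignment, frame=frame)


def table_from_labels(mask: BinaryBiovolume, frame: int = 0) -> CubeTable:
    """Build a table from an imported labeled mask: one record per object.

    Bypasses the grid — each label's voxel set is the record's region, so
    imported single-cell or object segmentations flow through the same
    cytometry as grid cubes.  Grid-dependent parameters (neighborhood,
    gradients) are not defined for such tables.
    """
    if mask.labels is None:
        raise ConfigurationError("mask carries no labels; use assign_voxels instead")
    labels = mask.labels
    present = np.unique(labels[labels > 0])
    counts = np.bincount(labels.ravel())
    df = pd.DataFrame(
        {
            "frame": frame,
            "cube_id": present,
            "i": -1,
            "j": -1,
            "k": -1,
            "region_voxels": counts[present],
            "fg_voxels": counts[present],
            "truncated": False,
        }
    )
    row_of_label = np.full(int(labels.max()) + 1, -1, dtype=np.int64)
    row_of_label[present] = np.arange(present.size)
    assignment = np.where(labels > 0, row_of_label[labels], -1)
    return CubeTable(df, None, mask.geometry, assignment=assignment, frame=frame)
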