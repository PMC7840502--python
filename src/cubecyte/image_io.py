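"""Reading TIFF stacks and masks; writing cube tables, global metric tables
and legacy VTK files for ParaView.

Voxel geometry is always supplied explicitly (from the run configuration),
never inferred from TIFF resolution tags, which are unreliable in practice;
this keeps analyses reproducible across export pipelines.

TIFF array layout convention (how this package writes and reads its own
stacks):  2D ``(y, x)``; 3D ``(z, y, x)``; 4D ``(c, z, y, x)``;
5D ``(t, c, z, y, x)``.
"""

from __future__ import annotations

import os
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import (
    BinaryBiovolume,
    ConfigurationError,
    DimensionError,
    IntensityStack,
    VoxelGeometry,
)
from .dissection import INDEX_COLUMNS, CubeGrid, CubeTable

#: float format preserving round-trips to at least 15 significant digits
CSV_FLOAT_FORMAT = "%.17g"


def read_stack(
    path,
    geometry: VoxelGeometry,
    channel: int = 0,
    frame: int = 0,
    channel_name: str | None = None,
) -> IntensityStack:
    """Read one channel/frame of a TIFF stack as an IntensityStack.

    2D images yield shape (1, ny, nx).  The requested channel and frame
    must exist in the file; voxel geometry comes from the sidecar config.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis, np.newaxis, np.newaxis, :, :]
    elif arr.ndim == 3:
        arr = arr[np.newaxis, np.newaxis, :, :, :]
    elif arr.ndim == 4:
        arr = arr[np.newaxis, :, :, :, :]
    elif arr.ndim != 5:
        raise ConfigurationError(f"unsupported TIFF dimensionality {arr.ndim}")
    n_frames, n_channels = arr.shape[:2]
    if not (0 <= frame < n_frames):
        raise ConfigurationError(
            f"frame {frame} out of range: file has {n_frames} frame(s)"
        )
    if not (0 <= channel < n_channels):
        raise ConfigurationError(
            f"channel {channel} out of range: file has {n_channels} channel(s)"
        )
    values = np.asarray(arr[frame, channel], dtype=float)
    return IntensityStack(
        values,
        geometry,
        channel_name=channel_name if channel_name is not None else str(channel + 1),
        frame_index=frame,
    )


def write_stack(stack: IntensityStack, path) -> None:
    """Write a single-channel stack as a multi-page TIFF (z pages)."""
    values = stack.values
    if np.issubdtype(values.dtype, np.floating):
        if np.allclose(values, np.round(values)) and values.max() < 2**16 and values.min() >= 0:
            values = np.round(values).astype(np.uint16)
        else:
            values = values.astype(np.float32)
    tifffile.imwrite(path, values, photometric="minisblack")


def read_mask(
    path, geometry: VoxelGeometry, expected_shape: tuple[int, int, int] | None = None
) -> BinaryBiovolume:
    """Read a pre-segmented binary or labeled mask.

    Nonzero voxels are foreground.  Distinct positive integers are kept as
    instance labels so imported single-cell or object segmentations can be
    quantified through the cube-table machinery.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such mask file: {path}")
    arr = tifffile.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        raise TypeError(
            "mask TIFF has float voxels; binarize or label it with integers first"
        )
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise DimensionError(f"mask must be 2D or 3D; got ndim={arr.ndim}")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise DimensionError(
            f"mask shape {arr.shape} does not match dataset shape {expected_shape}"
        )
    mask = arr != 0
    if not mask.any():
        warnings.warn(f"mask {path} contains no foreground voxels", stacklevel=2)
    distinct = np.unique(arr[arr > 0])
    labels = arr.astype(np.int64) if distinct.size > 1 else None
    return BinaryBiovolume(mask, geometry, labels=labels, provenance={"source": str(path)})


def write_mask(mask: BinaryBiovolume, path) -> None:
    arr = mask.labels if mask.labels is not None else mask.mask.astype(np.uint8)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.uint16), photometric="minisblack")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_cube_table(table: CubeTable, path) -> None:
    """Write the cube table as CSV: frame, cube_id, i, j, k, then one column
    per parameter in sorted order.  Missing values are literal "NaN"; floats
    round-trip to full precision."""
    if len(table) == 0:
        raise ConfigurationError("refusing to write an empty cube table")
    cols = INDEX_COLUMNS + sorted(table.parameters)
    table.df[cols].to_csv(
        path, index=False, na_rep="NaN", float_format=CSV_FLOAT_FORMAT
    )


def read_cube_table(path) -> pd.DataFrame:
    """Re-read an exported cube table (as a plain DataFrame)."""
    return pd.read_csv(path, na_values=["NaN"], float_precision="round_trip")


def write_global_metrics(frames: Sequence[pd.DataFrame] | pd.DataFrame, path) -> None:
    """Long-format global metrics CSV: frame, metric, value, units."""
    df = pd.concat(frames) if not isinstance(frames, pd.DataFrame) else frames
    df.to_csv(path, index=False, na_rep="NaN", float_format=CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

def export_vtk(table: CubeTable, grid: CubeGrid, params: Sequence[str], path) -> None:
    """Write the cube grid as a legacy ASCII VTK STRUCTURED_POINTS file.

    Point dimensions are (nx+1, ny+1, nz+1) for (nx, ny, nz) cubes; SPACING
    is the realized cube edge per axis in µm.  One CELL_DATA scalar array is
    written per requested parameter (NaN on unoccupied cubes) plus an
    "occupied" 0/1 array.  Cell ordering is x fastest, matching cube_id.
    Legacy ASCII (not XML) keeps the output hand-inspectable and byte-stable.
    """
    for p in params:
        if p not in table.df.columns:
            raise ConfigurationError(
                f"unknown parameter {p!r}; available: {sorted(table.parameters)}"
            )
    nx, ny, nz = grid.counts
    ex, ey, ez = grid.edge_lengths_um
    n_cells = grid.n_cubes
    cube_id = table.df["cube_id"].to_numpy()

    lines = [
        "# vtk DataFile Version 3.0",
        "cubecyte cube parameters",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {ex:.10g} {ey:.10g} {ez:.10g}",
        f"CELL_DATA {n_cells}",
    ]
    occupied = np.zeros(n_cells)
    occupied[cube_id] = 1.0
    arrays = [("occupied", occupied)]
    for p in params:
        full = np.full(n_cells, np.nan)
        full[cube_id] = table.df[p].to_numpy(dtype=float)
        arrays.append((p, full))
    for name, arr in arrays:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" if np.isfinite(v) else "nan" for v in arr)
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
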