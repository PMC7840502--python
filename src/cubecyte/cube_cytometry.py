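"""Per-cube cytometry: geometry, distances, intensity, texture, correlation
and neighborhood parameters, custom derived parameters, and gating.

With two fluorescence channels the standard parameter set totals 49 per
cube: 13 geometry, 5 neighborhood/derived, 8 intensity statistics per
channel, 5 gray-level co-occurrence texture statistics per channel, and 5
correlation parameters (3 pairwise channel correlations plus one
density–intensity correlation per channel).

All cube statistics are computed over the cube's *foreground* voxels only —
they describe the biomass, not the background; the fill fraction alone uses
the full (possibly truncated) cube region as denominator.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import (
    BinaryBiovolume,
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
    IntensityStack,
    VoxelGeometry,
)
from .dissection import CubeTable

MIN_TEXTURE_VOXELS = 8


# ---------------------------------------------------------------------------
# Distance fields
# ---------------------------------------------------------------------------

@dataclass
class DistanceFields:
    """Distance coordinates of the biovolume.

    d_surface      per-voxel Euclidean distance (µm) of foreground voxels to
                   the nearest background voxel ("distance to the biofilm
                   outer surface"); anisotropy-aware.
    com            center of mass of the biovolume, (z, y, x) in µm.
    com_projected  com with z set to 0 (projection onto the substratum).
    max_thickness  maximum column height of the biofilm, µm.
    """

    d_surface: np.ndarray
    com: np.ndarray
    com_projected: np.ndarray
    max_thickness: float
    substrate_mode: str = "attached"


def column_heights(mask: np.ndarray, dz: float) -> np.ndarray:
    """COMSTAT-convention column height map, µm: (1 + top foreground z)·dz
    per xy-column, ignoring interior gaps; 0 for empty columns."""
    nz = mask.shape[0]
    any_fg = mask.any(axis=0)
    top = nz - 1 - np.argmax(mask[::-1], axis=0)
    return np.where(any_fg, (top + 1) * dz, 0.0)


def compute_distance_fields(
    mask: BinaryBiovolume, substrate_mode: str = "attached"
) -> DistanceFields:
    """Euclidean distance transform of the foreground to the outer surface.

    The volume is padded with background on all faces except the z=0 face:
    in ``attached`` mode that face is treated as substratum contact, not
    outer surface, so a surface-attached biofilm's base contributes no
    surface distance.  ``floating`` mode (free aggregates) pads all six
    faces with background.
    """
    if substrate_mode not in {"attached", "floating"}:
        raise ConfigurationError(f"unknown substrate_mode {substrate_mode!r}")
    m = mask.mask
    if not m.any():
        raise DegenerateInputError("empty mask: distance fields undefined")
    g = mask.geometry
    padded = np.pad(m, 1, constant_values=False)
    if substrate_mode == "attached":
        # Replicate the z=0 slice below itself: the substratum plane is not
        # a background source.
        padded[0, 1:-1, 1:-1] = m[0]
    d = ndimage.distance_transform_edt(padded, sampling=g.spacing_zyx)
    d_surface = d[1:-1, 1:-1, 1:-1]

    zz, yy, xx = np.nonzero(m)
    com = np.array(
        [
            (zz.mean() + 0.5) * g.dz,
            (yy.mean() + 0.5) * g.dy,
            (xx.mean() + 0.5) * g.dx,
        ]
    )
    com_projected = com.copy()
    com_projected[0] = 0.0
    heights = column_heights(m, g.dz)
    return DistanceFields(
        d_surface=d_surface,
        com=com,
        com_projected=com_projected,
        max_thickness=float(heights.max()),
        substrate_mode=substrate_mode,
    )


def exposed_faces_area(mask: BinaryBiovolume, substrate_mode: str = "attached") -> np.ndarray:
    """Per-voxel exposed surface area (µm²): sum of the areas of the voxel's
    faces adjacent to background.  Out-of-volume neighbors count as
    background, except below the z=0 plane in attached mode (substratum)."""
    m = mask.mask
    g = mask.geometry
    padded = np.pad(m, 1, constant_values=False)
    if substrate_mode == "attached":
        padded[0, 1:-1, 1:-1] = m[0]
    face_area = {  # area of a face normal to each axis
        0: g.dx * g.dy,  # z-normal
        1: g.dx * g.dz,  # y-normal
        2: g.dy * g.dz,  # x-normal
    }
    core = (slice(1, -1),) * 3
    area = np.zeros(m.shape, dtype=float)
    for axis in range(3):
        for step in (-1, 1):
            neigh = np.roll(padded, step, axis=axis)[core]
            area += face_area[axis] * (m & ~neigh)
    return area


# ---------------------------------------------------------------------------
# Grouped helpers
# ---------------------------------------------------------------------------

def _fg_groups(table: CubeTable) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Row index and voxel coordinates of every foreground voxel with a record."""
    if table.assignment is None:
        raise ConfigurationError(
            "table has no voxel assignment (gated or deserialized tables "
            "cannot run voxel-level quantification)"
        )
    coords = np.nonzero(table.assignment >= 0)
    idx = table.assignment[coords]
    return idx, coords

def _group_mean(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    counts = np.bincount(idx, minlength=n)
    sums = np.bincount(idx, weights=values, minlength=n)
    with np.errstate(invalid="ignore"):
        return sums / counts


# ---------------------------------------------------------------------------
# Geometry parameters (13)
# ---------------------------------------------------------------------------

def quantify_geometry(
    table: CubeTable, mask: BinaryBiovolume, fields: DistanceFields
) -> CubeTable:
    """Add the 13 structural/positional parameters to each record."""
    if table.assignment is not None and table.assignment.shape != mask.shape:
        raise DimensionError("table assignment and mask shapes differ")
    g = table.geometry
    n = len(table)
    idx, (zz, yy, xx) = _fg_groups(table)
    counts = table.df["fg_voxels"].to_numpy(dtype=float)

    table.add_parameter(
        "fill_fraction", table.df["fg_voxels"] / table.df["region_voxels"]
    )
    table.add_parameter("foreground_voxel_count", counts)
    table.add_parameter("biovolume_um3", counts * g.voxel_volume_um3)

    cz = _group_mean(idx, (zz + 0.5) * g.dz, n)
    cy = _group_mean(idx, (yy + 0.5) * g.dy, n)
    cx = _group_mean(idx, (xx + 0.5) * g.dx, n)
    table.add_parameter("centroid_x_um", cx)
    table.add_parameter("centroid_y_um", cy)
    table.add_parameter("centroid_z_um", cz)

    table.add_parameter(
        "dist_surface_um", _group_mean(idx, fields.d_surface[zz, yy, xx], n)
    )
    table.add_parameter("dist_substrate_um", cz)
    com = fields.com
    table.add_parameter(
        "dist_com_um",
        np.sqrt((cz - com[0]) ** 2 + (cy - com[1]) ** 2 + (cx - com[2]) ** 2),
    )
    pcom = fields.com_projected
    table.add_parameter(
        "dist_com_projected_um",
        np.sqrt((cy - pcom[1]) ** 2 + (cx - pcom[2]) ** 2),
    )

    # Mean whole-biofilm column height over the distinct xy-columns the
    # cube occupies.
    heights = column_heights(mask.mask, g.dz)
    ny, nx = heights.shape
    col_key = idx * (ny * nx) + yy * nx + xx
    uniq = np.unique(col_key)
    u_idx = uniq // (ny * nx)
    u_col = uniq % (ny * nx)
    table.add_parameter(
        "local_thickness_um", _group_mean(u_idx, heights.ravel()[u_col], n)
    )

    area = exposed_faces_area(mask, fields.substrate_mode)
    exposed = np.bincount(idx, weights=area[zz, yy, xx], minlength=n)
    table.add_parameter("exposed_surface_area_um2", exposed)
    biovol = counts * g.voxel_volume_um3
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(biovol > 0, exposed / biovol, np.nan)
    table.add_parameter("local_surface_to_volume_um", ratio)
    return table


# ---------------------------------------------------------------------------
# Intensity parameters (8 per channel)
# ---------------------------------------------------------------------------

def quantify_intensity(table: CubeTable, stacks: Sequence[IntensityStack]) -> CubeTable:
    """Per-channel intensity statistics over each cube's foreground voxels:
    mean, population sd, cv, median, min, max, sum, range."""
    idx, (zz, yy, xx) = _fg_groups(table)
    n = len(table)
    for stack in stacks:
        if stack.shape != table.assignment.shape:
            raise DimensionError(
                f"channel {stack.channel_name!r} shape {stack.shape} does not "
                f"match mask shape {table.assignment.shape}"
            )
        c = stack.channel_name
        if c not in table.channels:
            table.channels.append(c)
        v = stack.values[zz, yy, xx].astype(float)
        mean = _group_mean(idx, v, n)
        mean_sq = _group_mean(idx, v * v, n)
        var = np.maximum(mean_sq - mean**2, 0.0)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / mean, np.nan)
        grouped = pd.Series(v).groupby(idx)
        median = grouped.median().reindex(range(n)).to_numpy()
        vmin = grouped.min().reindex(range(n)).to_numpy()
        vmax = grouped.max().reindex(range(n)).to_numpy()
        vsum = np.bincount(idx, weights=v, minlength=n)
        table.add_parameter(f"ch{c}_mean", mean)
        table.add_parameter(f"ch{c}_sd", sd)
        table.add_parameter(f"ch{c}_cv", cv)
        table.add_parameter(f"ch{c}_median", median)
        table.add_parameter(f"ch{c}_min", vmin)
        table.add_parameter(f"ch{c}_max", vmax)
        table.add_parameter(f"ch{c}_sum", vsum)
        table.add_parameter(f"ch{c}_range", vmax - vmin)
    return table


# ---------------------------------------------------------------------------
# Texture parameters (5 per channel)
# ---------------------------------------------------------------------------

def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    """Statistics of a normalized symmetric co-occurrence matrix."""
    levels = p.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    mu_i = float((p.sum(axis=1) * np.arange(levels)).sum())
    mu_j = float((p.sum(axis=0) * np.arange(levels)).sum())
    var_i = float((p.sum(axis=1) * (np.arange(levels) - mu_i) ** 2).sum())
    var_j = float((p.sum(axis=0) * (np.arange(levels) - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            ((p * (i - mu_i) * (j - mu_j)).sum()) / np.sqrt(var_i * var_j)
        )
    else:
        correlation = np.nan
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def cube_glcm(levels_array: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix of a quantized
    subvolume.  ``levels_array`` holds level indices, -1 for voxels outside
    the cube's foreground.  Offsets of ±1 voxel along each axis are pooled.
    Returns an all-zero matrix if no valid pair exists."""
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for axis in range(3):
        a = np.moveaxis(levels_array, axis, 0)[:-1].ravel()
        b = np.moveaxis(levels_array, axis, 0)[1:].ravel()
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        np.add.at(counts, (a[valid], b[valid]), 1.0)
        np.add.at(counts, (b[valid], a[valid]), 1.0)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def quantify_texture(
    table: CubeTable, stacks: Sequence[IntensityStack], levels: int = 8
) -> CubeTable:
    """Haralick-style texture statistics of each cube's foreground voxels.

    Intensities are quantized per cube to ``levels`` equal bins between the
    cube's min and max.  Cubes with fewer than 8 foreground voxels (or no
    co-occurring voxel pair) get NaN for all texture parameters.
    """
    idx, (zz, yy, xx) = _fg_groups(table)
    n = len(table)
    order = np.argsort(idx, kind="stable")
    idx_s, zs, ys, xs = idx[order], zz[order], yy[order], xx[order]
    bounds = np.searchsorted(idx_s, np.arange(n + 1))
    stat_names = ["contrast", "correlation", "energy", "homogeneity", "entropy"]
    for stack in stacks:
        c = stack.channel_name
        out = {s: np.full(n, np.nan) for s in stat_names}
        vals = stack.values.astype(float)
        for r in range(n):
            lo, hi = bounds[r], bounds[r + 1]
            if hi - lo < MIN_TEXTURE_VOXELS:
                continue
            z, y, x = zs[lo:hi], ys[lo:hi], xs[lo:hi]
            v = vals[z, y, x]
            vmin, vmax = v.min(), v.max()
            if vmax > vmin:
                q = np.minimum(
                    ((v - vmin) / (vmax - vmin) * levels).astype(int), levels - 1
                )
            else:
                q = np.zeros(v.size, dtype=int)
            z0, y0, x0 = z.min(), y.min(), x.min()
            sub = np.full(
                (z.max() - z0 + 1, y.max() - y0 + 1, x.max() - x0 + 1),
                -1,
                dtype=int,
            )
            sub[z - z0, y - y0, x - x0] = q
            p = cube_glcm(sub, levels)
            if p.sum() == 0:
                continue  # no adjacent voxel pair
            for s, val in _glcm_stats(p).items():
                out[s][r] = val
        for s in stat_names:
            table.add_parameter(f"ch{c}_glcm_{s}", out[s])
    return table


# ---------------------------------------------------------------------------
# Correlation parameters (3 per channel pair + 1 density correlation/channel)
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _moc(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def quantify_correlations(
    table: CubeTable, stacks: Sequence[IntensityStack]
) -> CubeTable:
    """Channel–channel correlations within each cube, and the correlation
    between fluorescence and local biomass density across each cube's
    27-cube neighborhood.

    Per unordered channel pair: Pearson, Spearman and Manders' overlap
    coefficient MOC = Σ(A·B)/√(ΣA²·ΣB²) over the cube's foreground voxels.
    Per channel: Pearson correlation between neighbor mean intensity and
    neighbor fill fraction across the occupied cubes among the 26 neighbors
    plus the cube itself (NaN with fewer than 3 points).  The within-cube
    density is a single number, hence the neighborhood definition.
    """
    idx, (zz, yy, xx) = _fg_groups(table)
    n = len(table)
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    bounds = np.searchsorted(idx_s, np.arange(n + 1))
    channel_vals = {
        s.channel_name: s.values[zz, yy, xx].astype(float)[order] for s in stacks
    }
    names = [s.channel_name for s in stacks]

    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            a_name, b_name = names[ai], names[bi]
            pear = np.full(n, np.nan)
            spear = np.full(n, np.nan)
            moc = np.full(n, np.nan)
            va, vb = channel_vals[a_name], channel_vals[b_name]
            for r in range(n):
                lo, hi = bounds[r], bounds[r + 1]
                a, b = va[lo:hi], vb[lo:hi]
                pear[r] = _pearson(a, b)
                if a.size >= 2 and a.std() > 0 and b.std() > 0:
                    spear[r] = stats.spearmanr(a, b).statistic
                moc[r] = _moc(a, b)
            table.add_parameter(f"ch{a_name}{b_name}_pearson", pear)
            table.add_parameter(f"ch{a_name}{b_name}_spearman", spear)
            table.add_parameter(f"ch{a_name}{b_name}_moc", moc)

    # Density correlation over the grid neighborhood.
    if table.grid is not None and "fill_fraction" in table.df.columns:
        nx, ny, nz = table.grid.counts
        row_grid = np.full((nz, ny, nx), -1, dtype=np.int64)
        kk = table.df["k"].to_numpy()
        jj = table.df["j"].to_numpy()
        ii = table.df["i"].to_numpy()
        row_grid[kk, jj, ii] = np.arange(n)
        fill = table.df["fill_fraction"].to_numpy()
        for c in names:
            mean_col = table.df[f"ch{c}_mean"].to_numpy()
            out = np.full(n, np.nan)
            for r in range(n):
                k0, j0, i0 = kk[r], jj[r], ii[r]
                rows = row_grid[
                    max(k0 - 1, 0) : k0 + 2,
                    max(j0 - 1, 0) : j0 + 2,
                    max(i0 - 1, 0) : i0 + 2,
                ].ravel()
                rows = rows[rows >= 0]
                if rows.size >= 3:
                    out[r] = _pearson(mean_col[rows], fill[rows])
            table.add_parameter(f"ch{c}_density_corr", out)
    else:
        for c in names:
            table.add_parameter(f"ch{c}_density_corr", np.full(n, np.nan))
    return table


# ---------------------------------------------------------------------------
# Neighborhood parameters (5)
# ---------------------------------------------------------------------------

def quantify_neighborhood(table: CubeTable, fields: DistanceFields) -> CubeTable:
    """Grid-context parameters: occupied neighbor count (0–26), mean
    neighbor fill, fill-gradient magnitude (µm⁻¹, central differences with
    unoccupied/outside cubes counted as density 0), relative height within
    the local column, and surface distance normalized by max thickness."""
    n = len(table)
    need = ("fill_fraction", "local_thickness_um", "dist_surface_um", "centroid_z_um")
    for p in need:
        if p not in table.df.columns:
            raise ConfigurationError(f"geometry parameter {p!r} missing; run quantify_geometry first")
    if table.grid is None:
        for p in (
            "occupied_neighbor_count",
            "neighborhood_mean_fill",
            "fill_gradient_magnitude",
        ):
            table.add_parameter(p, np.full(n, np.nan))
    else:
        nx, ny, nz = table.grid.counts
        occ = np.zeros((nz, ny, nx), dtype=float)
        fill_grid = np.zeros((nz, ny, nx), dtype=float)
        kk = table.df["k"].to_numpy()
        jj = table.df["j"].to_numpy()
        ii = table.df["i"].to_numpy()
        occ[kk, jj, ii] = 1.0
        fill_grid[kk, jj, ii] = table.df["fill_fraction"].to_numpy()
        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0.0
        n_occ = ndimage.convolve(occ, kernel, mode="constant", cval=0.0)
        fill_sum = ndimage.convolve(fill_grid, kernel, mode="constant", cval=0.0)
        cnt = np.rint(n_occ[kk, jj, ii])
        table.add_parameter("occupied_neighbor_count", cnt)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_fill = np.where(cnt > 0, fill_sum[kk, jj, ii] / cnt, np.nan)
        table.add_parameter("neighborhood_mean_fill", mean_fill)

        ex, ey, ez = table.grid.edge_lengths_um
        padded = np.pad(fill_grid, 1, constant_values=0.0)
        gz = (padded[2:, 1:-1, 1:-1] - padded[:-2, 1:-1, 1:-1]) / (2 * ez)
        gy = (padded[1:-1, 2:, 1:-1] - padded[1:-1, :-2, 1:-1]) / (2 * ey)
        gx = (padded[1:-1, 1:-1, 2:] - padded[1:-1, 1:-1, :-2]) / (2 * ex)
        gmag = np.sqrt(gz**2 + gy**2 + gx**2)
        table.add_parameter("fill_gradient_magnitude", gmag[kk, jj, ii])

    thick = table.df["local_thickness_um"].to_numpy()
    cz = table.df["centroid_z_um"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(thick > 0, cz / thick, np.nan)
    table.add_parameter("relative_height", rel)
    dmax = fields.max_thickness
    dsn = table.df["dist_surface_um"].to_numpy() / dmax if dmax > 0 else np.full(n, np.nan)
    table.add_parameter("dist_surface_normalized", dsn)
    return table


def quantify_all(
    table: CubeTable,
    mask: BinaryBiovolume,
    stacks: Sequence[IntensityStack],
    substrate_mode: str = "attached",
    texture_levels: int = 8,
) -> CubeTable:
    """Run the full per-cube parameter pipeline in the canonical order."""
    fields = compute_distance_fields(mask, substrate_mode)
    quantify_geometry(table, mask, fields)
    quantify_intensity(table, stacks)
    quantify_texture(table, stacks, levels=texture_levels)
    quantify_correlations(table, stacks)
    quantify_neighborhood(table, fields)
    return table


# ---------------------------------------------------------------------------
# Custom parameters: a small arithmetic expression language
# ---------------------------------------------------------------------------

class ParseError(ConfigurationError):
    """Raised with the offending position when an expression is malformed."""


_FUNCTIONS = {
    "log": np.log,
    "log10": np.log10,
    "exp": np.exp,
    "sqrt": np.sqrt,
    "abs": np.abs,
}

_TOKEN_OPS = {"+": "+", "-": "-", "*": "*", "/": "/", "^": "^",
              "×": "*", "÷": "/", "−": "-", "(": "(", ")": ")"}


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _TOKEN_OPS:
            tokens.append(("op", _TOKEN_OPS[ch], i))
            i += 1
        elif ch.isdigit() or ch == ".":
            j = i
            while j < len(text) and (text[j].isdigit() or text[j] in ".eE" or
                                     (text[j] in "+-" and text[j - 1] in "eE")):
                j += 1
            try:
                tokens.append(("num", float(text[i:j]), i))
            except ValueError:
                raise ParseError(f"invalid number {text[i:j]!r} at position {i}")
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("name", text[i:j], i))
            i = j
        else:
            raise ParseError(f"unexpected character {ch!r} at position {i}")
    return tokens


class ParamExpression:
    """Arithmetic expression over parameter names.

    Supports + − × ÷ ^ (also ASCII * /), unary minus, parentheses, numeric
    literals and the functions log, log10, exp, sqrt, abs.  Division by
    zero and logarithms of non-positive values evaluate to NaN per record.
    """

    def __init__(self, text: str):
        self.text = text
        self._tokens = _tokenize(text)
        self._pos = 0
        self.ast = self._parse_expr()
        if self._pos < len(self._tokens):
            _, val, pos = self._tokens[self._pos]
            raise ParseError(f"unexpected token {val!r} at position {pos}")
        self.names = sorted(self._collect_names(self.ast))

    # -- recursive descent --------------------------------------------------
    def _peek(self):
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise ParseError(f"unexpected end of expression {self.text!r}")
        self._pos += 1
        return tok

    def _parse_expr(self):
        node = self._parse_term()
        while (tok := self._peek()) and tok[0] == "op" and tok[1] in "+-":
            self._next()
            node = (tok[1], node, self._parse_term())
        return node

    def _parse_term(self):
        node = self._parse_unary()
        while (tok := self._peek()) and tok[0] == "op" and tok[1] in "*/":
            self._next()
            node = (tok[1], node, self._parse_unary())
        return node

    def _parse_unary(self):
        tok = self._peek()
        if tok and tok[0] == "op" and tok[1] == "-":
            self._next()
            return ("neg", self._parse_unary())
        return self._parse_power()

    def _parse_power(self):
        base = self._parse_atom()
        tok = self._peek()
        if tok and tok[0] == "op" and tok[1] == "^":
            self._next()
            return ("^", base, self._parse_unary())  # right-associative
        return base

    def _parse_atom(self):
        kind, val, pos = self._next()
        if kind == "num":
            return ("num", val)
        if kind == "name":
            nxt = self._peek()
            if nxt and nxt[0] == "op" and nxt[1] == "(":
                if val not in _FUNCTIONS:
                    raise ParseError(
                        f"unknown function {val!r} at position {pos}; "
                        f"available: {sorted(_FUNCTIONS)}"
                    )
                self._next()
                arg = self._parse_expr()
                close = self._next()
                if close[1] != ")":
                    raise ParseError(f"expected ')' at position {close[2]}")
                return ("call", val, arg)
            return ("name", val)
        if kind == "op" and val == "(":
            node = self._parse_expr()
            close = self._next()
            if close[1] != ")":
                raise ParseError(f"expected ')' at position {close[2]}")
            return node
        raise ParseError(f"unexpected token {val!r} at position {pos}")

    def _collect_names(self, node) -> set[str]:
        tag = node[0]
        if tag == "name":
            return {node[1]}
        if tag in {"num"}:
            return set()
        if tag in {"neg"}:
            return self._collect_names(node[1])
        if tag == "call":
            return self._collect_names(node[2])
        return self._collect_names(node[1]) | self._collect_names(node[2])

    def evaluate(self, columns: Mapping[str, np.ndarray]) -> np.ndarray:
        for name in self.names:
            if name not in columns:
                near = difflib.get_close_matches(name, list(columns), n=3)
                hint = f"; did you mean {near}?" if near else ""
                raise ConfigurationError(f"unknown parameter {name!r}{hint}")
        with np.errstate(all="ignore"):
            out = np.asarray(self._eval(self.ast, columns), dtype=float)
        out = np.where(np.isfinite(out), out, np.nan)
        return out

    def _eval(self, node, cols):
        tag = node[0]
        if tag == "num":
            return node[1]
        if tag == "name":
            return np.asarray(cols[node[1]], dtype=float)
        if tag == "neg":
            return -self._eval(node[1], cols)
        if tag == "call":
            return _FUNCTIONS[node[1]](self._eval(node[2], cols))
        a = self._eval(node[1], cols)
        b = self._eval(node[2], cols)
        if tag == "+":
            return a + b
        if tag == "-":
            return a - b
        if tag == "*":
            return a * b
        if tag == "/":
            return a / b
        if tag == "^":
            return np.power(a, b)
        raise ParseError(f"unknown node {tag!r}")


def add_custom_parameter(table: CubeTable, name: str, expression: str) -> CubeTable:
    """Evaluate an expression over existing parameters and append the result
    as a new parameter column."""
    if name in table.df.columns:
        raise ConfigurationError(f"parameter name {name!r} already in use")
    expr = ParamExpression(expression) if isinstance(expression, str) else expression
    cols = {p: table.df[p].to_numpy(dtype=float) for p in table.parameters}
    table.add_parameter(name, expr.evaluate(cols))
    return table


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangePredicate:
    parameter: str
    lower: float = -np.inf
    upper: float = np.inf
    inclusive_lower: bool = True
    inclusive_upper: bool = True

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ConfigurationError(
                f"gate on {self.parameter!r}: lower {self.lower} > upper {self.upper}"
            )


@dataclass(frozen=True)
class Gate:
    """Conjunction of range predicates selecting a cube subpopulation, by
    analogy with flow-cytometry gating."""

    predicates: tuple[RangePredicate, ...]

    @classmethod
    def from_ranges(cls, *ranges) -> "Gate":
        preds = []
        for r in ranges:
            if isinstance(r, RangePredicate):
                preds.append(r)
            else:
                preds.append(RangePredicate(*r))
        return cls(tuple(preds))


def gate(table: CubeTable, g: Gate, complement: bool = False) -> CubeTable:
    """Select the records satisfying every predicate of the gate.

    Records with NaN in any gated parameter are excluded from both the gate
    and its complement, so gate + complement partition the non-NaN records.
    """
    df = table.df
    valid = np.ones(len(df), dtype=bool)
    inside = np.ones(len(df), dtype=bool)
    for p in g.predicates:
        if p.parameter not in df.columns:
            raise ConfigurationError(f"unknown gate parameter {p.parameter!r}")
        v = df[p.parameter].to_numpy(dtype=float)
        valid &= ~np.isnan(v)
        lo = v >= p.lower if p.inclusive_lower else v > p.lower
        hi = v <= p.upper if p.inclusive_upper else v < p.upper
        inside &= lo & hi
    keep = valid & (~inside if complement else inside)
    if not keep.any():
        warnings.warn("gate selected no records", stacklevel=2)
    return table.copy_with(df[keep])
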