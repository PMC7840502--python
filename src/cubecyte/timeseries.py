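"""Time-series analysis: frame registration, cube lineage tracking, clonal
cluster sizes and spatiotemporal kymographs.

Cube identity across frames is positional: the grid is fixed and frames
are aligned by a rigid integer xy drift correction (surface-attached
biofilms do not translate in z).  Lineages follow a single-parent
largest-overlap rule with a lowest-id tie-break, which makes them
deterministic; the track graph is therefore a forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import BinaryBiovolume, ConfigurationError, DimensionError
from .dissection import CubeGrid, CubeTable


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_frames(
    masks: Sequence[BinaryBiovolume],
    max_shift: int = 20,
    enabled: bool = True,
) -> list[tuple[int, int]]:
    """Cumulative per-frame integer xy drift vectors.

    The drift of frame t relative to t−1 is the argmax of the centered 2D
    cross-correlation of the z-projected (voxel-count) masks, so that
    shifting frame t back by its drift aligns it with frame t−1.  Ties —
    e.g. a small colony growing symmetrically inside a larger one — break
    toward the smallest shift magnitude.  Returned drifts are accumulated
    relative to frame 0 and bounded per step by ``max_shift``.
    """
    if len(masks) < 2:
        raise ConfigurationError("registration needs at least 2 frames")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise DimensionError("all frames must share one shape")
    drifts = [(0, 0)]
    if not enabled:
        return [(0, 0)] * len(masks)
    cum = np.zeros(2, dtype=int)  # (sx, sy)
    for t in range(1, len(masks)):
        prev = masks[t - 1].mask.sum(axis=0).astype(float)
        cur = masks[t].mask.sum(axis=0).astype(float)
        if cur.sum() == 0 or prev.sum() == 0:
            warnings.warn(f"empty frame at t={t}: assuming zero drift", stacklevel=2)
            step = (0, 0)
        else:
            step = _best_shift(prev, cur, max_shift)
        cum = cum + np.asarray(step)
        drifts.append((int(cum[0]), int(cum[1])))
    return drifts


def _best_shift(prev: np.ndarray, cur: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Shift (sx, sy) maximizing corr(prev(y, x), cur(y + sy, x + sx))."""
    dp = prev - prev.mean()
    dc = cur - cur.mean()
    corr = signal.fftconvolve(dc, dp[::-1, ::-1], mode="full")
    ny, nx = prev.shape
    sy = np.arange(-(ny - 1), ny)
    sx = np.arange(-(nx - 1), nx)
    ok_y = np.abs(sy) <= max_shift
    ok_x = np.abs(sx) <= max_shift
    sub = corr[np.ix_(ok_y, ok_x)]
    syv, sxv = sy[ok_y], sx[ok_x]
    best = sub.max()
    ties = np.argwhere(sub >= best - 1e-9 * abs(best))
    # Smallest displacement first, then lexicographic, for determinism.
    order = sorted(
        (syv[iy] ** 2 + sxv[ix] ** 2, syv[iy], sxv[ix]) for iy, ix in ties
    )
    _, by, bx = order[0]
    return (int(bx), int(by))


def shift_volume(mask: np.ndarray, shift_xy: tuple[int, int]) -> np.ndarray:
    """Translate a volume by integer (sx, sy) voxels, zero-filling edges."""
    sx, sy = shift_xy
    out = np.zeros_like(mask)
    _, ny, nx = mask.shape
    ys_src = slice(max(0, -sy), min(ny, ny - sy))
    ys_dst = slice(max(0, sy), min(ny, ny + sy))
    xs_src = slice(max(0, -sx), min(nx, nx - sx))
    xs_dst = slice(max(0, sx), min(nx, nx + sx))
    out[:, ys_dst, xs_dst] = mask[:, ys_src, xs_src]
    return out


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

def track_cubes(
    tables: Sequence[CubeTable],
    masks: Sequence[BinaryBiovolume],
    drifts: Sequence[tuple[int, int]] | None = None,
) -> nx.DiGraph:
    """Connect cube lineages across consecutive frames.

    After drift correction, cube c at frame t is linked to cube c' at
    frame t+1 when their regions share at least one foreground voxel; each
    child keeps only its largest-overlap parent (ties go to the lowest
    parent cube_id).  Nodes are (frame, cube_id); edge weights are shared
    foreground voxel counts.  Roots are cubes with no parent.
    """
    if len(tables) != len(masks):
        raise ConfigurationError("one table per mask frame required")
    grid = tables[0].grid
    if grid is None:
        raise ConfigurationError("tracking requires grid-based tables")
    for t in tables:
        if t.grid is None or t.grid.counts != grid.counts or t.grid.span != grid.span:
            raise ConfigurationError("all frames must share one cube grid")
    if drifts is None:
        drifts = [(0, 0)] * len(masks)

    graph = nx.DiGraph()
    for t, table in enumerate(tables):
        for cid in table.df["cube_id"]:
            graph.add_node((t, int(cid)))

    cube_map = grid.cube_id_map()
    n_cubes = grid.n_cubes
    for t in range(len(masks) - 1):
        # Align both frames (and their cube identities) to frame-0 coords.
        m_a = shift_volume(masks[t].mask, (-drifts[t][0], -drifts[t][1]))
        m_b = shift_volume(masks[t + 1].mask, (-drifts[t + 1][0], -drifts[t + 1][1]))
        id_a = shift_volume(cube_map + 1, (-drifts[t][0], -drifts[t][1])) - 1
        id_b = shift_volume(cube_map + 1, (-drifts[t + 1][0], -drifts[t + 1][1])) - 1
        both = m_a & m_b & (id_a >= 0) & (id_b >= 0)
        if not both.any():
            continue
        pa = id_a[both].astype(np.int64)
        cb = id_b[both].astype(np.int64)
        pair_counts = np.bincount(pa * n_cubes + cb)
        pairs = np.flatnonzero(pair_counts)
        parents = pairs // n_cubes
        children = pairs % n_cubes
        weights = pair_counts[pairs]
        # Single largest-overlap parent per child; lowest parent id on ties.
        order = np.lexsort((parents, -weights, children))
        chosen_child = set()
        for o in order:
            ch = int(children[o])
            if ch in chosen_child:
                continue
            chosen_child.add(ch)
            graph.add_edge(
                (t, int(parents[o])), (t + 1, ch), overlap_voxels=int(weights[o])
            )
    return graph


def track_edge_list(graph: nx.DiGraph) -> pd.DataFrame:
    """Edge-list export: frame, parent_id, child_id, overlap_voxels."""
    rows = [
        {
            "frame": p[0],
            "parent_id": p[1],
            "child_id": c[1],
            "overlap_voxels": d["overlap_voxels"],
        }
        for p, c, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["frame", "parent_id", "child_id", "overlap_voxels"])


# ---------------------------------------------------------------------------
# Clonal clusters
# ---------------------------------------------------------------------------

def clonal_cluster_sizes(
    table: CubeTable,
    channel_a: str,
    channel_b: str,
    min_fraction: float = 0.9,
) -> dict[str, list[float]]:
    """Sizes (µm³) of connected clusters of cubes dominated by one strain.

    A cube is labeled with channel a when ch_a_mean/(ch_a_mean + ch_b_mean)
    >= min_fraction (and symmetrically for b); otherwise it is mixed and
    belongs to no cluster.  Clusters are 26-connected components on the
    cube grid; sizes sum the member cubes' biovolume.
    """
    if table.grid is None:
        raise ConfigurationError("clonal clusters require a grid-based table")
    for c in (channel_a, channel_b):
        if f"ch{c}_mean" not in table.df.columns:
            raise ConfigurationError(f"channel mean ch{c}_mean missing from table")
    if not (0.5 < min_fraction <= 1.0):
        raise ConfigurationError("min_fraction must be in (0.5, 1]")
    a = table.df[f"ch{channel_a}_mean"].to_numpy(dtype=float)
    b = table.df[f"ch{channel_b}_mean"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = a / (a + b)
    vol = table.df["biovolume_um3"].to_numpy(dtype=float)
    nx_, ny_, nz_ = table.grid.counts
    kk = table.df["k"].to_numpy()
    jj = table.df["j"].to_numpy()
    ii = table.df["i"].to_numpy()

    out: dict[str, list[float]] = {}
    structure = np.ones((3, 3, 3), dtype=bool)
    for name, dominant in (
        (channel_a, frac_a >= min_fraction),
        (channel_b, (1 - frac_a) >= min_fraction),
    ):
        occ = np.zeros((nz_, ny_, nx_), dtype=bool)
        volg = np.zeros((nz_, ny_, nx_), dtype=float)
        sel = dominant & ~np.isnan(frac_a)
        occ[kk[sel], jj[sel], ii[sel]] = True
        volg[kk[sel], jj[sel], ii[sel]] = vol[sel]
        labels, n_comp = ndimage.label(occ, structure=structure)
        sizes = ndimage.sum_labels(volg, labels, index=np.arange(1, n_comp + 1))
        out[name] = sorted((float(s) for s in np.atleast_1d(sizes)), reverse=True)
    return out


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """(distance bin) × (time or volume bin) matrix of an aggregated cube
    parameter.  Cells without contributing foreground voxels are NaN with
    weight 0."""

    x_coords: np.ndarray  # frame indices or per-column biovolume
    y_edges: np.ndarray  # distance-coordinate bin edges, µm
    values: np.ndarray  # shape (n_ybins, n_x)
    weights: np.ndarray  # foreground voxels contributing per cell
    param: str = ""
    axis_param: str = ""
    x_axis: str = "time"

    def __post_init__(self) -> None:
        ny = len(self.y_edges) - 1
        if self.values.shape != (ny, len(self.x_coords)):
            raise DimensionError("kymograph matrix shape inconsistent with bins")

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_csv(self, path) -> None:
        """CSV matrix with bin-edge header rows."""
        with open(path, "w", newline="") as fh:
            fh.write("# x_coords," + ",".join(f"{x:.10g}" for x in self.x_coords) + "\n")
            fh.write("# y_edges," + ",".join(f"{e:.10g}" for e in self.y_edges) + "\n")
            pd.DataFrame(self.values).to_csv(fh, header=False, index=False, na_rep="NaN")


def kymograph(
    tables: Sequence[CubeTable],
    param: str,
    axis_param: str,
    bin_um: float,
    x_axis: str = "time",
) -> Kymograph:
    """Aggregate a cube parameter into (distance bin) × (frame) cells.

    Cell values are foreground-voxel-weighted means, so sparse edge cubes
    do not dominate their bin.  With ``x_axis="biovolume"`` the column
    coordinate is the frame's total cube biovolume instead of the frame
    index (columns remain one per frame; biovolume is monotone for growing
    biofilms, making it a valid reparametrization of time).
    """
    if x_axis not in {"time", "biovolume"}:
        raise ConfigurationError("x_axis must be 'time' or 'biovolume'")
    if bin_um <= 0:
        raise ConfigurationError("bin_um must be > 0")
    for t in tables:
        for p in (param, axis_param):
            if p not in t.df.columns:
                raise ConfigurationError(f"parameter {p!r} missing from a frame table")

    axis_all = np.concatenate([t.df[axis_param].to_numpy(dtype=float) for t in tables])
    axis_all = axis_all[~np.isnan(axis_all)]
    if axis_all.size == 0:
        raise ConfigurationError(f"axis parameter {axis_param!r} is all-NaN")
    lo = np.floor(axis_all.min() / bin_um) * bin_um
    hi = np.ceil(axis_all.max() / bin_um) * bin_um
    if hi <= lo:
        hi = lo + bin_um
    y_edges = np.arange(lo, hi + 0.5 * bin_um, bin_um)
    n_y = len(y_edges) - 1

    values = np.full((n_y, len(tables)), np.nan)
    weights = np.zeros((n_y, len(tables)))
    x_coords = np.zeros(len(tables))
    for t, table in enumerate(tables):
        ax = table.df[axis_param].to_numpy(dtype=float)
        pv = table.df[param].to_numpy(dtype=float)
        w = table.df["fg_voxels"].to_numpy(dtype=float)
        ok = ~np.isnan(ax) & ~np.isnan(pv)
        bins = np.clip(((ax[ok] - lo) / bin_um).astype(int), 0, n_y - 1)
        wsum = np.bincount(bins, weights=w[ok], minlength=n_y)
        vsum = np.bincount(bins, weights=(pv * w)[ok], minlength=n_y)
        with np.errstate(invalid="ignore"):
            col = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1), np.nan)
        values[:, t] = col
        weights[:, t] = wsum
        if x_axis == "biovolume":
            x_coords[t] = float(table.df["biovolume_um3"].sum())
        else:
            x_coords[t] = t
    return Kymograph(x_coords, y_edges, values, weights, param, axis_param, x_axis)


def normalize_kymograph(k_num: Kymograph, k_den: Kymograph) -> Kymograph:
    """Cell-wise ratio of two kymographs with identical binning, e.g. a
    reporter normalized to a constitutively expressed channel."""
    if (
        len(k_num.x_coords) != len(k_den.x_coords)
        or len(k_num.y_edges) != len(k_den.y_edges)
        or not np.allclose(k_num.y_edges, k_den.y_edges)
    ):
        raise DimensionError("kymograph binning mismatch")
    den = k_den.values
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(np.isnan(den) | (den <= 0), np.nan, k_num.values / den)
    return Kymograph(
        k_num.x_coords.copy(),
        k_num.y_edges.copy(),
        ratio,
        np.minimum(k_num.weights, k_den.weights),
        param=f"{k_num.param}/{k_den.param}",
        axis_param=k_num.axis_param,
        x_axis=k_num.x_axis,
    )
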