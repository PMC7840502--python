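"""Whole-biofilm (global) parameters.

Three families:

* COMSTAT-compatible structure metrics (biovolume, thickness variants,
  roughness coefficient, substratum coverage, face-counted surface area,
  surface-to-volume ratio).  Column height follows the COMSTAT convention
  ``(1 + highest foreground z index) * dz``, ignoring interior gaps.
* Colocalization between two channels (Pearson, Manders' overlap
  coefficient, Manders' M1/M2, binarized volume overlap fractions and
  relative biovolume abundances).
* 3D spatial correlation functions of binary masks, with cluster-size and
  separation-distance summaries.

Correlation functions use per-lag valid-pair normalization (biofilm imaging
windows are not periodic, so no wraparound) and anisotropy-aware shell
averaging of the physical lag lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from skimage import measure

from .core import (
    BinaryBiovolume,
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
    IntensityStack,
    VoxelGeometry,
)
from .cube_cytometry import column_heights, exposed_faces_area, _pearson, _moc
from .dissection import CubeTable
from .segmentation import intensity_histogram, threshold_otsu


@dataclass
class GlobalMetrics:
    """Named scalar whole-biofilm parameters with units and provenance."""

    values: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, name: str, value: float, unit: str = "") -> None:
        self.values[name] = float(value)
        self.units[name] = unit

    def update(self, other: "GlobalMetrics") -> None:
        self.values.update(other.values)
        self.units.update(other.units)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_frame(self, frame: int = 0) -> pd.DataFrame:
        """Long-format table: frame, metric, value, units."""
        return pd.DataFrame(
            {
                "frame": frame,
                "metric": list(self.values),
                "value": [self.values[k] for k in self.values],
                "units": [self.units.get(k, "") for k in self.values],
            }
        )


def global_structure(
    mask: BinaryBiovolume, substrate_mode: str = "attached"
) -> GlobalMetrics:
    """COMSTAT-style structural parameters of the whole biovolume.

    The roughness coefficient is the normalized mean absolute deviation of
    occupied-column heights, Ra* = (1/N) Σ |L_i − L̄| / L̄ — zero for a
    perfectly flat biofilm.  Mean thickness is reported both over all
    columns of the field of view and over biomass-occupied columns only,
    since COMSTAT distinguishes the two.
    """
    m = mask.mask
    if not m.any():
        raise DegenerateInputError("empty mask: global structure undefined")
    g = mask.geometry
    out = GlobalMetrics(provenance={"substrate_mode": substrate_mode})
    out.add("biovolume_um3", mask.biovolume_um3, "µm³")

    heights = column_heights(m, g.dz)
    occupied = heights[heights > 0]
    out.add("max_thickness_um", heights.max(), "µm")
    out.add("mean_thickness_all_um", heights.mean(), "µm")
    out.add("mean_thickness_biomass_um", occupied.mean(), "µm")
    out.add("substratum_coverage", m[0].mean(), "")
    lbar = occupied.mean()
    out.add("roughness_coefficient", np.abs(occupied - lbar).mean() / lbar, "")

    area = exposed_faces_area(mask, substrate_mode).sum()
    out.add("exposed_surface_area_um2", area, "µm²")
    out.add("surface_to_biovolume_um_inv", area / mask.biovolume_um3, "µm⁻¹")
    out.add("surface_area_mesh_um2", _mesh_area(m, g), "µm²")
    return out


def _mesh_area(m: np.ndarray, g: VoxelGeometry) -> float:
    """Marching-cubes isosurface area; complements the face-counted area,
    which overestimates smooth surfaces by voxelization."""
    padded = np.pad(m.astype(float), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=g.spacing_zyx
        )
        return float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        return float("nan")


def colocalization(
    stack_a: IntensityStack,
    stack_b: IntensityStack,
    mask: BinaryBiovolume,
    level_a: float | None = None,
    level_b: float | None = None,
) -> GlobalMetrics:
    """Voxel-level colocalization of two channels inside the biovolume.

    Binarization levels default to per-channel Otsu thresholds computed on
    the within-mask intensities.  Relative abundances sum to 1 exactly.
    """
    if stack_a.shape != stack_b.shape or stack_a.shape != mask.shape:
        raise DimensionError("channel stacks and mask must share one shape")
    if not mask.mask.any():
        raise DegenerateInputError("empty mask: colocalization undefined")
    a = stack_a.values[mask.mask].astype(float)
    b = stack_b.values[mask.mask].astype(float)
    na, nb = stack_a.channel_name, stack_b.channel_name
    out = GlobalMetrics(provenance={"channels": (na, nb)})

    if a.max() == 0 or b.max() == 0:
        warnings.warn("a channel is identically zero inside the mask", stacklevel=2)
        for name in ("pearson", "moc", "manders_m1", "manders_m2"):
            out.add(name, np.nan, "")
    else:
        out.add("pearson", _pearson(a, b), "")
        out.add("moc", _moc(a, b), "")
        if level_a is None:
            level_a = threshold_otsu(intensity_histogram(a))
        if level_b is None:
            level_b = threshold_otsu(intensity_histogram(b))
        out.add("manders_m1", a[b > level_b].sum() / a.sum(), "")
        out.add("manders_m2", b[a > level_a].sum() / b.sum(), "")

    if level_a is None or level_b is None:  # zero channel: binarize at 0
        level_a = 0.0 if level_a is None else level_a
        level_b = 0.0 if level_b is None else level_b
    bin_a = a > level_a
    bin_b = b > level_b
    inter = np.count_nonzero(bin_a & bin_b)
    n_a, n_b = np.count_nonzero(bin_a), np.count_nonzero(bin_b)
    out.add("overlap_fraction_a", inter / n_a if n_a else np.nan, "")
    out.add("overlap_fraction_b", inter / n_b if n_b else np.nan, "")
    if n_a + n_b:
        rel_a = n_a / (n_a + n_b)
        out.add("relative_abundance_a", rel_a, "")
        out.add("relative_abundance_b", 1.0 - rel_a, "")
    else:
        out.add("relative_abundance_a", np.nan, "")
        out.add("relative_abundance_b", np.nan, "")
    out.provenance.update({"level_a": float(level_a), "level_b": float(level_b)})
    return out


@dataclass
class CorrelationProfile:
    """Shell-averaged spatial correlation versus physical lag distance.

    Bin 0 holds the zero lag alone (r = 0); bin i > 0 pools lags with
    physical length in ((i−1)·dr, i·dr], pair-count weighted.  For the
    autocorrelation the profile is normalized so value(0) = 1.
    """

    r_um: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    kind: str = "auto"  # auto | cross

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_um) <= 0):
            raise ConfigurationError("r bins must be strictly increasing")


def spatial_correlation(
    mask_a: BinaryBiovolume,
    mask_b: BinaryBiovolume | None,
    dr_um: float,
    rmax_um: float,
) -> CorrelationProfile:
    """3D spatial (cross-)covariance of binary masks, shell-averaged.

    The indicator fields are centered over the analysis window
    (δA = A − mean A); the covariance at every integer voxel lag is the sum
    of δA·δB over the valid in-window voxel pairs, divided by the number of
    such pairs.  Lags are then pooled into shells by physical length.
    The FFT route here is checked against a direct-sum oracle in tests.
    """
    if dr_um <= 0:
        raise ConfigurationError("dr_um must be > 0")
    if rmax_um < dr_um:
        raise ConfigurationError("rmax_um must be >= dr_um")
    kind = "auto" if mask_b is None else "cross"
    if mask_b is None:
        mask_b = mask_a
    if mask_a.shape != mask_b.shape:
        raise DimensionError("masks must share one shape")
    g = mask_a.geometry
    a = mask_a.mask.astype(float)
    b = mask_b.mask.astype(float)
    da = a - a.mean()
    db = b - b.mean()

    # Full linear cross-correlation: lag axes run -(n-1) .. n-1.
    corr = signal.fftconvolve(da, db[::-1, ::-1, ::-1], mode="full")
    shape = a.shape
    lags = [np.arange(-(n - 1), n) for n in shape]
    pair_counts = 1.0
    for ax, n in enumerate(shape):
        c = (n - np.abs(lags[ax])).astype(float)
        pair_counts = pair_counts * c.reshape([-1 if i == ax else 1 for i in range(3)])
    with np.errstate(invalid="ignore"):
        cov = corr / pair_counts

    lz = lags[0][:, None, None] * g.dz
    ly = lags[1][None, :, None] * g.dy
    lx = lags[2][None, None, :] * g.dx
    r = np.sqrt(lz**2 + ly**2 + lx**2)

    r_available = r.max()
    if rmax_um > r_available:
        warnings.warn(
            f"rmax {rmax_um} µm exceeds the window ({r_available:.3g} µm); truncated",
            stacklevel=2,
        )
        rmax_um = r_available

    keep = r <= rmax_um
    rk = r[keep]
    ck = cov[keep]
    nk = pair_counts[keep]
    # Bin 0: exact zero lag; bin i>0: ((i-1)dr, i*dr].
    bins = np.where(rk == 0, 0, np.ceil(rk / dr_um).astype(int))
    n_bins = int(bins.max()) + 1
    wsum = np.bincount(bins, weights=nk, minlength=n_bins)
    vsum = np.bincount(bins, weights=ck * nk, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        values = vsum / wsum
    centers = np.concatenate([[0.0], (np.arange(1, n_bins) - 0.5) * dr_um])

    norm = np.sqrt(da.var() * db.var()) if kind == "cross" else da.var()
    if norm > 0:
        values = values / norm
    defined = wsum > 0
    return CorrelationProfile(
        r_um=centers[defined],
        values=values[defined],
        pair_counts=wsum[defined],
        kind=kind,
    )


def correlation_summaries(profile: CorrelationProfile) -> GlobalMetrics:
    """Cluster size and separation distance estimators.

    cluster_size_um: smallest r where the autocorrelation first falls below
    1/e, linearly interpolated between bins.  separation_um: r of the first
    local maximum of the cross-correlation at r > 0.  NaN (with a warning)
    when no crossing or maximum exists within the profile.
    """
    out = GlobalMetrics(provenance={"kind": profile.kind})
    r, v = profile.r_um, profile.values
    if profile.kind == "auto":
        target = 1.0 / np.e
        cluster = np.nan
        for i in range(1, len(v)):
            if np.isnan(v[i]) or np.isnan(v[i - 1]):
                continue
            if v[i - 1] >= target > v[i]:
                frac = (v[i - 1] - target) / (v[i - 1] - v[i])
                cluster = r[i - 1] + frac * (r[i] - r[i - 1])
                break
        if np.isnan(cluster):
            warnings.warn("autocorrelation never crosses 1/e within rmax", stacklevel=2)
        out.add("cluster_size_um", cluster, "µm")
    else:
        sep = np.nan
        start = 1 if r[0] == 0 else 0
        for i in range(start + 1, len(v) - 1):
            if v[i] > v[i - 1] and v[i] >= v[i + 1]:
                sep = r[i]
                break
        if np.isnan(sep):
            warnings.warn("no interior maximum of the cross-correlation", stacklevel=2)
        out.add("separation_um", sep, "µm")
    return out


def summarize_cube_parameters(table: CubeTable) -> GlobalMetrics:
    """Distribution summaries (mean, population sd, median, q1, q3; NaN
    excluded, linear-interpolation quantiles) of every cube parameter —
    five global metrics per cube parameter."""
    if len(table) == 0:
        raise DegenerateInputError("empty cube table")
    out = GlobalMetrics()
    for p in table.parameters:
        v = table.df[p].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            for s in ("mean", "sd", "median", "q1", "q3"):
                out.add(f"{p}_{s}", np.nan)
            continue
        out.add(f"{p}_mean", v.mean())
        out.add(f"{p}_sd", v.std())
        out.add(f"{p}_median", np.median(v))
        out.add(f"{p}_q1", np.quantile(v, 0.25))
        out.add(f"{p}_q3", np.quantile(v, 0.75))
    return out
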