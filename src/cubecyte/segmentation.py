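"""Semantic segmentation of the biofilm biovolume.

Every voxel is classified as biomass vs. background by (optional) filtering
followed by a global intensity threshold.  Four automatic threshold
selectors are provided — Otsu, Ridler–Calvard iterative intermeans, robust
background, and maximum-correlation thresholding — plus a manual level.
Foreground is defined as intensity *strictly greater* than the level, so a
manual level equal to the image maximum yields an empty mask.

Histogram-based selectors (Otsu, MCT) operate on 256 equal-width bins
spanning the observed [min, max] range, which matches common practice for
8/16-bit microscopy data and keeps brute-force oracle scans tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import (
    BinaryBiovolume,
    ConfigurationError,
    DegenerateInputError,
    IntensityStack,
)

DEFAULT_BINS = 256


@dataclass(frozen=True)
class IntensityHistogram:
    """Binned intensity distribution used by the threshold criteria."""

    edges: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # length n_bins, non-negative integers

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.counts) + 1:
            raise ConfigurationError("histogram edges must outnumber counts by one")
        if np.any(np.diff(self.edges) <= 0):
            raise ConfigurationError("histogram edges must be strictly increasing")

    @property
    def n_nonempty(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class SegmentationConfig:
    """Settings for the segment() pipeline.

    method          one of otsu | ridler_calvard | robust_background | mct | manual
    manual_level    intensity level, required iff method == "manual"
    filter_type     none | median | gaussian (applied before thresholding)
    filter_size_um  physical radius (median) or sigma (gaussian) in µm
    min_object_voxels  despeckle: remove 26-connected components smaller than this
    fill_holes      fill holes per z-slice (2D fill; avoids sealing vertical channels)
    """

    method: str = "otsu"
    manual_level: Optional[float] = None
    filter_type: str = "none"
    filter_size_um: float = 0.0
    min_object_voxels: int = 0
    fill_holes: bool = False
    trim_fraction: float = 0.05
    k_sd: float = 2.0
    rc_tol: Optional[float] = None

    def __post_init__(self) -> None:
        methods = {"otsu", "ridler_calvard", "robust_background", "mct", "manual"}
        if self.method not in methods:
            raise ConfigurationError(
                f"unknown segmentation method {self.method!r}; choose from {sorted(methods)}"
            )
        if self.method == "manual" and self.manual_level is None:
            raise ConfigurationError("manual segmentation requires manual_level")
        if self.filter_type not in {"none", "median", "gaussian"}:
            raise ConfigurationError(f"unknown filter {self.filter_type!r}")
        if self.filter_size_um < 0:
            raise ConfigurationError("filter size must be >= 0")
        if self.min_object_voxels < 0:
            raise ConfigurationError("min_object_voxels must be >= 0")


def intensity_histogram(values: np.ndarray, bins: int = DEFAULT_BINS) -> IntensityHistogram:
    """Histogram with ``bins`` equal-width bins spanning [min, max]."""
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        # Single nonempty bin; thresholding callers reject this downstream.
        edges = np.array([vmin, vmin + 1.0])
        counts = np.array([values.size])
        return IntensityHistogram(edges, counts)
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    return IntensityHistogram(edges, counts)


def threshold_otsu(hist: IntensityHistogram) -> float:
    """Otsu's criterion: the level maximizing the between-class variance

        sigma_b^2(t) = w0(t) w1(t) (mu0(t) - mu1(t))^2

    where w0, w1 are the class weights and mu0, mu1 the class means of the
    voxels below/above the candidate level t.  Candidate levels are the
    interior bin edges; ties are broken toward the lowest level.
    """
    if hist.n_nonempty < 2:
        raise DegenerateInputError(
            "constant image: automatic thresholding undefined; use a manual level"
        )
    counts = hist.counts.astype(float)
    centers = hist.centers
    total = counts.sum()
    # Cut after bin t-1: class 0 = bins [0, t), class 1 = bins [t, end)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    tsum = (counts * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (tsum - csum) / w1
        sigma_b2 = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b2 = np.where(np.isfinite(sigma_b2), sigma_b2, -np.inf)
    best = int(np.argmax(sigma_b2))  # argmax returns the first (lowest) maximizer
    return float(hist.edges[best + 1])


def threshold_ridler_calvard(
    values: np.ndarray, tol: Optional[float] = None, max_iter: int = 1000
) -> float:
    """Iterative intermeans threshold.

    Starting from the global mean, iterate
    ``T <- (mean(values <= T) + mean(values > T)) / 2`` until the change is
    below ``tol`` (default: 1e-6 of the intensity range).
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateInputError("constant image: Ridler-Calvard threshold undefined")
    if tol is None:
        tol = 1e-6 * (vmax - vmin)
    if tol <= 0:
        raise ConfigurationError("tol must be > 0")
    t = float(values.mean())
    for _ in range(max_iter):
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            # All mass on one side; nudge to the midpoint of the range.
            t_new = 0.5 * (vmin + vmax)
        else:
            t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def threshold_robust_background(
    values: np.ndarray, trim_fraction: float = 0.05, k_sd: float = 2.0
) -> float:
    """Robust background threshold.

    Discards the dimmest and brightest ``trim_fraction`` of voxels and sets
    the level at ``mean + k_sd * sd`` of the remainder, so a minority of
    bright biomass voxels cannot inflate the background estimate.
    """
    if not (0 <= trim_fraction < 0.5):
        raise ConfigurationError("trim_fraction must satisfy 0 <= f < 0.5")
    if k_sd <= 0:
        raise ConfigurationError("k_sd must be > 0")
    values = np.sort(np.asarray(values, dtype=float).ravel())
    n = values.size
    cut = int(np.floor(n * trim_fraction))
    rest = values[cut : n - cut] if cut > 0 else values
    if rest.size == 0:
        raise DegenerateInputError("trimming removed all voxels")
    return float(rest.mean() + k_sd * rest.std())


def threshold_mct(values: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Maximum-correlation threshold.

    Scans the interior edges of a ``bins``-bin histogram and returns the
    level maximizing the Pearson correlation between the gray values and
    their binarization (intensity > level).  Ties break toward the lowest
    level.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.min() == values.max():
        raise DegenerateInputError("constant image: MCT threshold undefined")
    hist = intensity_histogram(values, bins=bins)
    candidates = hist.edges[1:-1]
    n = values.size
    mu = values.mean()
    sigma = values.std()
    srt = np.sort(values)
    best_level = None
    best_corr = -np.inf
    for t in candidates:
        n_above = n - np.searchsorted(srt, t, side="right")
        if n_above == 0 or n_above == n:
            continue
        p = n_above / n
        mu_above = srt[n - n_above :].mean()
        # corr(I, 1[I>t]) = p (mu_above - mu) / (sigma * sqrt(p(1-p)))
        corr = p * (mu_above - mu) / (sigma * np.sqrt(p * (1 - p)))
        if corr > best_corr:
            best_corr = corr
            best_level = float(t)
    if best_level is None:
        raise DegenerateInputError("no valid candidate level for MCT")
    return best_level


def preprocess(stack: IntensityStack, cfg: SegmentationConfig) -> IntensityStack:
    """Apply the configured denoising filter before thresholding.

    Physical filter sizes (µm) are converted to per-axis voxel extents, so
    the effective kernel is isotropic in physical space even on anisotropic
    confocal stacks.
    """
    if cfg.filter_type == "none":
        return stack
    if cfg.filter_size_um < 0:
        raise ConfigurationError("filter size must be >= 0")
    g = stack.geometry
    if cfg.filter_type == "median":
        half = [max(0, round(cfg.filter_size_um / p)) for p in g.spacing_zyx]
        if stack.is_2d:
            half[0] = 0
        size = tuple(2 * h + 1 for h in half)
        out = ndimage.median_filter(stack.values, size=size, mode="nearest")
    else:  # gaussian
        sigma = [cfg.filter_size_um / p for p in g.spacing_zyx]
        if stack.is_2d:
            sigma[0] = 0.0
        out = ndimage.gaussian_filter(
            stack.values.astype(float), sigma=sigma, mode="nearest"
        )
    return IntensityStack(out, g, stack.channel_name, stack.frame_index)


def _choose_level(values: np.ndarray, cfg: SegmentationConfig) -> float:
    if cfg.method == "manual":
        return float(cfg.manual_level)
    if cfg.method == "otsu":
        return threshold_otsu(intensity_histogram(values))
    if cfg.method == "ridler_calvard":
        return threshold_ridler_calvard(values, tol=cfg.rc_tol)
    if cfg.method == "robust_background":
        return threshold_robust_background(values, cfg.trim_fraction, cfg.k_sd)
    if cfg.method == "mct":
        return threshold_mct(values)
    raise ConfigurationError(f"unknown method {cfg.method!r}")


def remove_small_objects(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Drop 26-connected components smaller than min_voxels (8-connected in 2D)."""
    if min_voxels <= 1 or not mask.any():
        return mask
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def fill_holes_per_slice(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background per z-slice (2D), never across slices, so
    genuine vertical channels through the biofilm are not sealed."""
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndimage.binary_fill_holes(mask[z])
    return out


def segment(stack: IntensityStack, cfg: SegmentationConfig) -> BinaryBiovolume:
    """Full segmentation pipeline: filter -> threshold -> despeckle -> fill.

    The chosen threshold level is recorded in the result's provenance
    metadata for inspection and for the run's JSON sidecar.
    """
    filtered = preprocess(stack, cfg)
    level = _choose_level(filtered.values, cfg)
    mask = filtered.values > level
    if not mask.any():
        warnings.warn(
            f"segmentation with level {level} produced an empty mask", stacklevel=2
        )
    mask = remove_small_objects(mask, cfg.min_object_voxels)
    if cfg.fill_holes:
        mask = fill_holes_per_slice(mask)
    return BinaryBiovolume(
        mask,
        stack.geometry,
        provenance={
            "method": cfg.method,
            "threshold": level,
            "filter": cfg.filter_type,
            "filter_size_um": cfg.filter_size_um,
            "min_object_voxels": cfg.min_object_voxels,
            "fill_holes": cfg.fill_holes,
            "channel": stack.channel_name,
            "frame": stack.frame_index,
        },
    )
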