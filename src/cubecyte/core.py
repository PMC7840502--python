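"""Core domain types and errors shared across the package.

Conventions used everywhere:

* Voxel arrays are indexed ``(z, y, x)`` with ``z = 0`` the plane adjacent
  to the substratum (attachment surface).
* Coordinates are 0-based; the physical position of the center of voxel
  ``(z, y, x)`` is ``((z + 0.5) * dz, (y + 0.5) * dy, (x + 0.5) * dx)`` in µm.
* ``NaN`` is the universal missing-value token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class CubecyteError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CubecyteError):
    """A parameter, config key or request is invalid or out of bounds."""


class DegenerateInputError(CubecyteError):
    """The input carries too little information for the requested operation
    (e.g. a constant image handed to an automatic thresholding algorithm)."""


class DimensionError(CubecyteError):
    """Array shapes or voxel geometries that must agree do not."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel in µm along each axis.

    Confocal stacks are typically anisotropic: the z spacing (often ~1 µm)
    exceeds the lateral pixel pitch, so dz is carried separately.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(
                    f"voxel geometry {name}={v!r} must be strictly positive and finite"
                )

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Sampling tuple in array axis order, for scipy/skimage calls."""
        return (self.dz, self.dy, self.dx)


@dataclass
class IntensityStack:
    """One channel / one frame of raw or filtered voxel intensities.

    ``values`` is a 3D array (z, y, x); 2D images are stored with a
    degenerate leading axis of length 1.
    """

    values: np.ndarray
    geometry: VoxelGeometry
    channel_name: str = "1"
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[np.newaxis, :, :]
        if self.values.ndim != 3:
            raise DimensionError(
                f"intensity stack must be 3D (z, y, x); got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("intensity stack contains non-finite values")
        if self.frame_index < 0:
            raise ConfigurationError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_2d(self) -> bool:
        return self.values.shape[0] == 1


@dataclass
class BinaryBiovolume:
    """The segmented biomass mask on the same voxel grid as its source stack.

    ``labels`` optionally retains the instance labels of an imported
    pre-segmented mask (distinct positive integers), enabling object-level
    cytometry through the same table machinery as grid cubes.
    """

    mask: np.ndarray
    geometry: VoxelGeometry
    labels: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim == 2:
            self.mask = self.mask[np.newaxis, :, :]
        if self.mask.ndim != 3:
            raise DimensionError(
                f"binary biovolume must be 3D (z, y, x); got ndim={self.mask.ndim}"
            )
        self.mask = self.mask.astype(bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.mask.shape:
                raise DimensionError("label array shape must match mask shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def biovolume_um3(self) -> float:
        return self.foreground_count * self.geometry.voxel_volume_um3
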