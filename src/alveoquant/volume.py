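"""Core image containers: physically calibrated 3-D intensity and label volumes.

Axis order is fixed as ``(z, y, x)`` with the origin at the array corner and
0-based indices.  Every physical measurement in the package goes through
:class:`VoxelSpacing` (micrometres per voxel step) so that anisotropic
confocal stacks — typically coarser in ``z`` than in-plane — are handled
without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelSpacing", "ImageVolume", "LabelVolume"]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical length of one voxel step along each axis, in micrometres.

    Attributes
    ----------
    dz, dy, dx : float
        Step along ``z`` (optical axis), ``y`` and ``x``; all strictly
        positive.
    """

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelSpacing.{name} must be finite and > 0, got {v!r}")

    @property
    def tuple(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dz * self.dy * self.dx


def _check_grid(data: np.ndarray, what: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"{what} must be a rank-3 (z, y, x) array, got rank {data.ndim}")
    return data


@dataclass
class ImageVolume:
    """One channel of a 3-D stack with physical voxel spacing.

    ``data`` is indexed ``(z, y, x)`` and holds non-negative, finite
    intensities.  ``channel_name`` is a free-text tag such as ``"membrane"``,
    ``"nuclear"`` or ``"marker:EdU"``.
    """

    data: np.ndarray
    spacing: VoxelSpacing
    channel_name: str = "channel"

    def __post_init__(self) -> None:
        self.data = _check_grid(self.data, "ImageVolume.data")
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValueError(f"ImageVolume.data must be numeric, got {self.data.dtype}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume.data contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Integer-labelled partition of a grid; 0 is background.

    The label set need not be contiguous.  Labels index segmented cells or
    nuclei; physical volumes are always voxel counts times
    ``spacing.voxel_volume``.
    """

    labels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.labels = _check_grid(self.labels, "LabelVolume.labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"LabelVolume.labels must be integer, got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("LabelVolume.labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_ids(self) -> np.ndarray:
        """Sorted array of non-background labels present."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.spacing)
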