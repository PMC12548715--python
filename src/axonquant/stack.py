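"""Core image container: a 3D intensity grid with isotropic physical voxels.

All volumes in this package use ``(z, y, x)`` axis order, 0-based voxel
indices, and world coordinates in micrometres measured from the centre of
voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeStack:
    """A single-channel 3D fluorescence stack with isotropic voxels.

    Parameters
    ----------
    voxels
        3D array of non-negative, finite intensities, ``(z, y, x)`` order.
    voxel_size_um
        Physical edge length of one voxel in micrometres. One scalar: the
        acquisition geometry this package models produces isotropic voxels
        (equal sampling in-plane and along z).
    channel_name
        Free-text channel identifier (e.g. ``"EGFP"``, ``"CR"``).
    """

    voxels: np.ndarray
    voxel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if not np.isscalar(self.voxel_size_um) or not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be a positive scalar (isotropic voxels)")
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.all(np.isfinite(self.voxels)):
                raise ValueError("intensities must be finite")
            if np.any(self.voxels < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume_um3(self) -> float:
        """Physical volume of the stack: product of axis extents in um."""
        return float(np.prod(self.voxels.shape) * self.voxel_size_um**3)

    def astype_float(self) -> np.ndarray:
        return self.voxels.astype(np.float64, copy=False)
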