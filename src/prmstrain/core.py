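"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Volume arrays are indexed ``(x, y, z)`` in the order of the NIfTI
  array axes; sequences add a leading frame axis ``(t, x, y, z)``.
* Physical position of voxel ``(i, j, k)`` is ``(i, j, k) * spacing``
  (0-based indices, spacing in mm).
* Displacements are stored in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass
class VolumeSequence:
    """A 3D+t scalar ultrasound sequence with physical metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_frames, nx, ny, nz)`` with non-negative
        intensities.
    spacing:
        Voxel size in mm, one value per spatial axis.
    frame_interval:
        Time between volumes in seconds.  The clinical acquisitions this
        models run at a volume rate of 1.5 Hz, i.e. ~0.667 s per volume.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame_interval: float = 1.0 / 1.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InputError(
                f"volume sequence must be 4D (t, x, y, z); got {self.data.ndim}D"
            )
        if self.data.shape[0] < 2:
            raise InputError("volume sequence needs at least 2 frames")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise InputError(f"spacing must be 3 positive values; got {self.spacing}")
        if self.frame_interval <= 0:
            raise InputError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(n) for n in self.data.shape[1:])

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def voxel_positions_mm(
    voxels: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Physical positions (mm) of integer voxel indices ``(n, 3)``."""
    return np.asarray(voxels, dtype=float) * np.asarray(spacing, dtype=float)


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise InputError(f"{what} must share one grid; got {a.shape} vs {b.shape}")
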