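"""In-memory voxel volume container.

Coordinate convention used throughout the package: axis order is (z, y, x)
with 0-based voxel indices, and the world coordinate of voxel ``(i, j, k)``
is ``origin_mm + (i, j, k) * spacing_mm`` (millimetres).  Volumes are always
used in stored voxel space; no reorientation is performed on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A scalar 3-D voxel grid (HU or Gy) with anisotropic spacing.

    Parameters
    ----------
    values
        3-D array, axis order (z, y, x).
    spacing_mm
        Per-axis voxel size in mm, strictly positive.
    origin_mm
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("spacing_mm and origin_mm must have 3 components")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_coordinates(self) -> np.ndarray:
        """Per-voxel world coordinates, shape (3, nz, ny, nx), in mm."""
        grids = np.meshgrid(
            *[np.arange(n, dtype=np.float64) for n in self.shape], indexing="ij"
        )
        return np.stack(
            [g * s + o for g, s, o in zip(grids, self.spacing_mm, self.origin_mm)]
        )

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing_mm, self.origin_mm)
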