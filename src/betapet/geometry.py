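"""Voxel grid geometry shared by phantoms, reconstructions and masks.

World coordinates are in millimetres. Voxel indices are 0-based, ordered
(slice, row, col) = (z, y, x), and a voxel's value is attributed to its
center. The world->voxel mapping is the affine
``world = origin + index * voxel_size`` applied per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "ActivityVolume"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3-D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (slices, rows, cols).
    voxel_size : tuple of float
        Voxel pitch in mm along (slice thickness, row pitch, col pitch).
    origin : tuple of float, optional
        World-mm position of the center of voxel (0, 0, 0). Defaults to
        placing the grid center at the world origin.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(voxel) != 3:
            raise ValueError("shape and voxel_size must have length 3")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(v <= 0 for v in voxel):
            raise ValueError(f"all voxel sizes must be > 0, got {voxel}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        if self.origin is None:
            origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel))
        else:
            origin = tuple(float(o) for o in self.origin)
            if len(origin) != 3:
                raise ValueError("origin must have length 3")
        object.__setattr__(self, "origin", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinate arrays (z, y, x), each of shape ``self.shape``."""
        z, y, x = (self.axis_coords(a) for a in range(3))
        return np.meshgrid(z, y, x, indexing="ij")

    def world_to_voxel(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a world point (no rounding)."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def voxel_to_world(self, index) -> np.ndarray:
        i = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + i * np.asarray(self.voxel_size)

    def contains_index(self, index) -> bool:
        i = np.asarray(index)
        return bool(np.all(i >= 0) and np.all(i < np.asarray(self.shape)))


@dataclass
class ActivityVolume:
    """3-D activity-concentration image in kBq/mL on a :class:`GridGeometry`."""

    grid: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("activity values must be finite")
        if np.any(values < 0):
            raise ValueError("activity values must be nonnegative")
        self.values = values

    @classmethod
    def zeros(cls, grid: GridGeometry) -> "ActivityVolume":
        return cls(grid, np.zeros(grid.shape))

    def copy(self) -> "ActivityVolume":
        return ActivityVolume(self.grid, self.values.copy())
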