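"""Voxel grids in world (mm) coordinates.

Conventions used throughout the package: axes are (x = left-right,
y = posterior-anterior, z = inferior-superior), arrays are indexed
``values[ix, iy, iz]``, world position of voxel ``(0, 0, 0)`` center is
``origin``, and voxel ``i`` sits at ``origin + i * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Shape/spacing description of a grid centered on the world origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ValueError(f"grid shape must be >= (16,16,16), got {self.shape}")
        if any(h <= 0 for h in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(-(n - 1) / 2.0 * h for n, h in zip(self.shape, self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            o + h * np.arange(n)
            for n, h, o in zip(self.shape, self.spacing, self.origin)
        )

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def zeros(self, dtype=np.float64) -> "VoxelGrid":
        return VoxelGrid(self.spacing, self.origin, np.zeros(self.shape, dtype=dtype))

    def wrap(self, values: np.ndarray) -> "VoxelGrid":
        if tuple(values.shape) != tuple(self.shape):
            raise ValueError("array shape does not match grid spec")
        return VoxelGrid(self.spacing, self.origin, values)


@dataclass
class VoxelGrid:
    """A scalar field sampled on a regular grid.

    ``spacing`` and ``origin`` are in mm; ``values`` is indexed (x, y, z).
    """

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = tuple(float(h) for h in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(h <= 0 for h in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if self.values.ndim != 3 or any(s < 16 for s in self.values.shape):
            raise ValueError("values must be a 3-D array with shape >= (16,16,16)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            o + h * np.arange(n)
            for n, h, o in zip(self.shape, self.spacing, self.origin)
        )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.spacing, self.origin, self.values.copy())
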