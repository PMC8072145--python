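"""Containers and discretization shared by all radiomic feature classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "ROIMask", "QuantizedROI", "discretize", "UNIQUE_DIRECTIONS"]


@dataclass
class VoxelGrid:
    intensities: np.ndarray                    # 3D float array
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm per axis

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")


@dataclass
class ROIMask:
    mask: np.ndarray  # 3D binary array

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxel")


@dataclass
class QuantizedROI:
    """Discretized gray levels: integer array over the full grid, 0 outside ROI."""

    levels: np.ndarray  # int array, 1..Ng inside mask, 0 outside
    mask: np.ndarray    # bool
    ng: int
    bin_width: float

    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(grid: VoxelGrid, roi: ROIMask, bin_width: float = 25.0) -> QuantizedROI:
    """Min-referenced fixed-bin-width quantization of in-ROI intensities.

    ``level = floor((I - min_roi)/bin_width) + 1``; Ng is the largest level.
    A constant ROI quantizes to a single level (Ng = 1).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if grid.intensities.shape != roi.mask.shape:
        raise ValueError("mask shape must match volume shape")
    vals = grid.intensities[roi.mask]
    levels = np.zeros(grid.intensities.shape, dtype=np.int64)
    levels[roi.mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return QuantizedROI(
        levels=levels, mask=roi.mask, ng=int(levels.max()), bin_width=float(bin_width)
    )


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    # the 13 offsets covering all 26 neighbors up to sign
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d > (0, 0, 0):
                    dirs.append(d)
    return tuple(dirs)


UNIQUE_DIRECTIONS: tuple[tuple[int, int, int], ...] = _unique_directions()
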