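"""Minimal 3D volume container shared by every stage of the pipeline.

A :class:`Volume` is a scalar grid with isotropic-or-not voxel spacing in mm.
Axis 0 is the axial (slice) direction throughout the package; masks are
half-open voxel sets represented as boolean arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["Volume", "same_grid", "require_same_grid"]


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing.

    Parameters
    ----------
    data : np.ndarray
        3D array, axis order (slice, row, column).
    voxel_mm : tuple of float
        Voxel edge lengths in mm for each axis.
    units : str
        Free-text physical units ("HU", "cm^-1", "a.u.", ...).
    """

    data: np.ndarray
    voxel_mm: Tuple[float, float, float]
    units: str = "a.u."
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be 3 positive floats, got {self.voxel_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_mm)) / 1000.0

    def like(self, data: np.ndarray, units: str | None = None) -> "Volume":
        """New Volume on the same grid."""
        return Volume(data, self.voxel_mm, units if units is not None else self.units,
                      dict(self.meta))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_mm, self.units, dict(self.meta))


def same_grid(a: Volume, b: Volume) -> bool:
    return a.shape == b.shape and np.allclose(a.voxel_mm, b.voxel_mm)


def require_same_grid(*vols: Volume) -> None:
    ref = vols[0]
    for v in vols[1:]:
        if not same_grid(ref, v):
            raise ValueError(
                f"grid mismatch: {ref.shape}@{ref.voxel_mm} vs {v.shape}@{v.voxel_mm}")
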