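"""In-memory CT volume container.

Arrays are indexed ``(x, y, z)`` with ``z`` along the scanner axis (superior
positive).  Physical positions are measured in millimetres at voxel centers:
``pos_mm = origin_mm + index * spacing``.  All geometry in this package is done
in mm space so that results are invariant to the (typically anisotropic)
acquisition spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D scalar grid of Hounsfield units with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        HU values. Finite.
    spacing : tuple of float
        Voxel pitch (sx, sy, sz) in mm, strictly positive.
    origin_mm : tuple of float
        mm position of the center of voxel (0, 0, 0).
    axes : str
        Axis-order convention tag; only "xyz" is produced by this package.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if any(n < m for n, m in zip(self.values.shape, (8, 8, 4))):
            raise ValueError(f"volume too small: shape {self.values.shape}, need >= (8, 8, 4)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """mm position of voxel-center(s); `idx` is (..., 3), may be fractional."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing)

    def mm_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel index of mm position(s)."""
        pos_mm = np.asarray(pos_mm, dtype=float)
        return (pos_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing)

    def contains_mm(self, pos_mm: np.ndarray) -> bool:
        """True if a mm position falls inside the field of view (voxel extents)."""
        idx = self.mm_to_index(pos_mm)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    def like(self, values: np.ndarray) -> "ImageVolume":
        """New volume with the same geometry and different values."""
        return ImageVolume(values, self.spacing, self.origin_mm, self.axes)


def grid_coords_mm(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin_mm: tuple[float, float, float],
    lo: tuple[int, int, int] | None = None,
    hi: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis mm coordinates of voxel centers for a (sub-)grid.

    Returns three 1D arrays (x, y, z).  `lo`/`hi` bound a half-open index
    sub-box; defaults cover the whole grid.
    """
    lo = (0, 0, 0) if lo is None else lo
    hi = shape if hi is None else hi
    return tuple(
        origin_mm[a] + np.arange(lo[a], hi[a], dtype=float) * spacing[a] for a in range(3)
    )  # type: ignore[return-value]
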