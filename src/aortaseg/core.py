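"""Core spatial containers shared by every stage of the pipeline.

Coordinate convention (used everywhere, documented only here):

* Arrays are indexed ``data[ix, iy, iz]``.
* Axis ``x`` is the transverse (left-right) direction, axis ``y`` is
  anteroposterior (AP), axis ``z`` is the axial (slice) direction with the
  slice index growing superior -> inferior.
* Voxel indices are 0-based; boxes are half-open ``[lo, hi)``.
* World coordinates (mm) of a voxel *center*: ``world = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Volume", "LabelMask", "LABELS", "BACKGROUND", "LUMEN", "WALL_ILT"]

#: Label semantics for multi-class masks.
BACKGROUND, LUMEN, WALL_ILT = 0, 1, 2
LABELS = (BACKGROUND, LUMEN, WALL_ILT)


@dataclass
class Volume:
    """A scalar 3D voxel grid with physical geometry.

    Parameters
    ----------
    data:
        3D array of scalars (image intensities or per-class probabilities).
    spacing:
        Voxel size in mm per axis ``(sx, sy, sz)``; strictly positive.
    origin:
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume payload must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def extent_mm(self) -> np.ndarray:
        """Physical extent (mm) per axis, ``shape * spacing``."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (n, 3) or (3,) to world mm."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new payload."""
        return replace(self, data=data)


@dataclass
class LabelMask(Volume):
    """Integer label grid over {0 background, 1 lumen, 2 wall/thrombus}.

    Shares geometry semantics with :class:`Volume`; values are validated to
    stay within the known label set.
    """

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.allclose(
                self.data, np.round(self.data)
            ):
                self.data = self.data.astype(np.uint8)
            else:
                raise ValueError("LabelMask payload must be integer-valued")
        super().__post_init__()
        present = np.unique(self.data)
        if not np.isin(present, LABELS).all():
            raise ValueError(f"LabelMask contains labels outside {LABELS}: {present}")

    def binary(self, cls: int) -> np.ndarray:
        """Boolean mask of one class."""
        return self.data == cls

    def foreground(self) -> np.ndarray:
        """Boolean mask of any non-background class."""
        return self.data != BACKGROUND


def same_geometry(a: Volume, b: Volume, atol: float = 1e-6) -> bool:
    """True when two volumes share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def require_same_geometry(a: Volume, b: Volume) -> None:
    if not same_geometry(a, b):
        raise ValueError(
            f"geometry mismatch: {a.shape}/{a.spacing}/{a.origin} vs "
            f"{b.shape}/{b.spacing}/{b.origin}"
        )
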