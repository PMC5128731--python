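"""Shared containers for CT volumes and binary masks.

Conventions
-----------
* Arrays are indexed ``(slice, row, col)`` (3D) or ``(row, col)`` (2D),
  0-based, row index increasing downward in the displayed image.
* Intensities are Hounsfield-like: air ~ -1000, aerated lung ~ -800,
  soft tissue ~ 0..60, cortical bone >= +200.
* ``spacing`` is millimetres per voxel along each axis, ``(dz, dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """A 3D CT intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels:
        ``(n_slices, rows, cols)`` float array in Hounsfield-like units.
    spacing:
        ``(dz, dy, dx)`` in mm, all strictly positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 0.7, 0.7)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3D (slice, row, col)")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        """In-plane spacing ``(dy, dx)`` in mm."""
        return self.spacing[1], self.spacing[2]


def as_bool_mask(mask: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Coerce to a boolean array, optionally checking shape against ``like``."""
    out = np.asarray(mask, dtype=bool)
    if like is not None and out.shape != np.asarray(like).shape:
        raise ValueError(f"mask shape {out.shape} != expected {np.asarray(like).shape}")
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks (1.0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)


@dataclass
class SliceLog:
    """Structured per-slice processing record emitted by the pipeline."""

    index: int
    phi_deg: float = 0.0
    aligned: bool = False
    separation_method: str = "none_needed"
    n_concaves_corrected: int = 0
    status: str = "ok"
    detail: str = ""
    extras: dict = field(default_factory=dict)
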