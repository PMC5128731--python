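"""Volumetric and surface evaluation metrics for segmentation pairs.

Volume metrics compare voxel counts of an automatic mask against a manual
reference: VD (volume difference, cm^3), RVD (relative volume difference,
percent, sign distinguishing over- from under-segmentation) and VOE (volume
overlap error, percent, 100 * (1 - Jaccard)).

Surface metrics compare the boundary voxel sets: a surface voxel is a mask
voxel with at least one background face-neighbor (voxels outside the array
count as background).  With d(v, S) the shortest Euclidean distance in mm
from voxel center v to surface S, the symmetric mean (ASD), quadratic mean
(RMSD) and maximum (MSD, symmetric Hausdorff) over both surfaces are
reported.  Distances come from an exact Euclidean distance transform with
anisotropic sampling; ASD <= RMSD <= MSD always (power-mean inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMask, EmptyReference

__all__ = [
    "SegMetrics",
    "surface_voxels",
    "compute_volume_metrics",
    "compute_surface_metrics",
    "cumulative_distance_distribution",
    "evaluate_masks",
]


@dataclass(frozen=True)
class SegMetrics:
    """The seven-number evaluation record for one volume pair."""

    vd_cm3: float
    rvd_pct: float
    voe_pct: float
    asd_mm: float
    rmsd_mm: float
    msd_mm: float
    over_segmented: bool  # RVD > 0

    def as_dict(self) -> dict:
        return {
            "VD_cm3": self.vd_cm3,
            "RVD_pct": self.rvd_pct,
            "VOE_pct": self.voe_pct,
            "ASD_mm": self.asd_mm,
            "RMSD_mm": self.rmsd_mm,
            "MSD_mm": self.msd_mm,
            "over_segmented": self.over_segmented,
        }


def _check_pair(auto: np.ndarray, manu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(auto, dtype=bool)
    m = np.asarray(manu, dtype=bool)
    if a.shape != m.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {m.shape}")
    return a, m


def _spacing_for(mask: np.ndarray, spacing) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) == 1:
        spacing = spacing * mask.ndim
    if len(spacing) != mask.ndim:
        raise ValueError("spacing length must match mask dimensionality")
    return spacing


def compute_volume_metrics(
    auto: np.ndarray, manu: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[float, float, float]:
    """Return (VD in cm^3, RVD in percent, VOE in percent).

    The reference volume in RVD's denominator is the manual mask.

    Raises
    ------
    EmptyReference
        If the manual mask is empty.
    """
    a, m = _check_pair(auto, manu)
    spacing = _spacing_for(a, spacing)
    n_manu = int(m.sum())
    if n_manu == 0:
        raise EmptyReference("manual reference mask is empty")
    n_auto = int(a.sum())
    voxel_mm3 = float(np.prod(spacing))
    vd_cm3 = (n_auto - n_manu) * voxel_mm3 / 1000.0
    rvd_pct = 100.0 * (n_auto - n_manu) / n_manu
    union = int(np.logical_or(a, m).sum())
    inter = int(np.logical_and(a, m).sum())
    voe_pct = 100.0 * (1.0 - inter / union) if union else 0.0
    return vd_cm3, rvd_pct, voe_pct


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one background face-neighbor (the array
    border counts as background)."""
    m = np.asarray(mask, dtype=bool)
    struct = ndi.generate_binary_structure(m.ndim, 1)
    interior = ndi.binary_erosion(m, structure=struct, border_value=0)
    return m & ~interior


def _surface_distances(
    a: np.ndarray, m: np.ndarray, spacing
) -> tuple[np.ndarray, np.ndarray]:
    """d(s, S(m)) for s in S(a), and vice versa, in mm."""
    sa = surface_voxels(a)
    sm = surface_voxels(m)
    dt_to_m = ndi.distance_transform_edt(~sm, sampling=spacing)
    dt_to_a = ndi.distance_transform_edt(~sa, sampling=spacing)
    return dt_to_m[sa], dt_to_a[sm]


def compute_surface_metrics(
    auto: np.ndarray, manu: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[float, float, float]:
    """Return (ASD, RMSD, MSD) in mm; symmetric in the two masks.

    Raises
    ------
    EmptyMask
        If either mask is empty.
    """
    a, m = _check_pair(auto, manu)
    spacing = _spacing_for(a, spacing)
    if not a.any() or not m.any():
        raise EmptyMask("surface metrics need two non-empty masks")
    d_am, d_ma = _surface_distances(a, m, spacing)
    n = d_am.size + d_ma.size
    asd = (d_am.sum() + d_ma.sum()) / n
    rmsd = np.sqrt((np.square(d_am).sum() + np.square(d_ma).sum()) / n)
    msd = max(d_am.max(), d_ma.max())
    return float(asd), float(rmsd), float(msd)


def cumulative_distance_distribution(
    auto: np.ndarray,
    manu: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    bin_width_mm: float = 0.5,
) -> list[tuple[float, float]]:
    """Empirical CDF of the distance from the automatic surface to the
    manual surface, as (bin upper edge in mm, cumulative probability)
    pairs; the last probability is 1.
    """
    a, m = _check_pair(auto, manu)
    spacing = _spacing_for(a, spacing)
    if not a.any() or not m.any():
        raise EmptyMask("distance distribution needs two non-empty masks")
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    d_am, _ = _surface_distances(a, m, spacing)
    n_bins = max(int(np.ceil((d_am.max() + 1e-12) / bin_width_mm)), 1)
    edges = np.arange(1, n_bins + 1) * bin_width_mm
    cum = np.searchsorted(np.sort(d_am), edges, side="right") / d_am.size
    cum[-1] = 1.0
    return [(float(e), float(c)) for e, c in zip(edges, cum)]


def evaluate_masks(
    auto: np.ndarray, manu: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> SegMetrics:
    """Full seven-number comparison of an automatic mask against a manual
    reference."""
    vd, rvd, voe = compute_volume_metrics(auto, manu, spacing)
    asd, rmsd, msd = compute_surface_metrics(auto, manu, spacing)
    return SegMetrics(
        vd_cm3=vd,
        rvd_pct=rvd,
        voe_pct=voe,
        asd_mm=asd,
        rmsd_mm=rmsd,
        msd_mm=msd,
        over_segmented=rvd > 0,
    )
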