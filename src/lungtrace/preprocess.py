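"""Scan alignment and chest-mask extraction.

A tilted scan (patient lying on their side) breaks the diagonal start-point
search used downstream, so the in-plane inclination is estimated from the
bone pixels: the first principal component of their (x, y) coordinates gives
the body's lateral axis, and the signed angle phi between that axis and the
positive x-axis is the tilt.  Following clinical practice only scans with
|phi| beyond a gate (default 15 degrees) are actually rotated.

The chest (skin-boundary) mask is the classic threshold pipeline: Otsu
binarization, morphological opening to drop salt noise / bed sheet / scanner
shell, largest connected component, hole filling so the lungs lie inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, transform

from .errors import NoBonePixels, NoForeground

__all__ = [
    "AlignmentResult",
    "compute_principal_angle",
    "align_image",
    "otsu_threshold",
    "chest_mask",
    "ALIGN_GATE_DEG",
    "DEFAULT_BONE_THRESHOLD",
]

#: Rotation is applied only when |phi| exceeds this gate (degrees).
ALIGN_GATE_DEG = 15.0

#: Cortical-bone cutoff in Hounsfield-like units.
DEFAULT_BONE_THRESHOLD = 200.0


@dataclass(frozen=True)
class AlignmentResult:
    """Estimated in-plane tilt of one slice.

    ``mu`` is the unit first principal component of the bone-pixel (x, y)
    cloud (x = column, y = row), sign-normalized to a non-negative
    x-projection; ``phi_deg`` is its signed angle to the positive x-axis in
    (-90, 90]; ``applied`` records whether the rotation gate was exceeded;
    ``rotation_matrix`` is the 2x2 matrix that maps untilted (x, y) offsets
    to tilted ones.
    """

    phi_deg: float
    applied: bool
    mu: tuple[float, float]
    rotation_matrix: np.ndarray

    @property
    def gate_deg(self) -> float:
        return ALIGN_GATE_DEG


def compute_principal_angle(
    slice_img: np.ndarray,
    bone_threshold: float = DEFAULT_BONE_THRESHOLD,
    gate_deg: float = ALIGN_GATE_DEG,
) -> AlignmentResult:
    """Estimate the tilt angle phi from bone pixels by PCA.

    Raises
    ------
    NoBonePixels
        If fewer than two pixels exceed ``bone_threshold``.
    """
    img = np.asarray(slice_img, dtype=float)
    rows, cols = np.nonzero(img > bone_threshold)
    if rows.size < 2:
        raise NoBonePixels(
            f"{rows.size} pixel(s) above bone threshold {bone_threshold}"
        )
    # x = column, y = row (image coordinates, y increasing downward)
    xy = np.column_stack([cols.astype(float), rows.astype(float)])
    xy -= xy.mean(axis=0)
    cov = xy.T @ xy / xy.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    mu = eigvecs[:, np.argmax(eigvals)]
    if mu[0] < 0 or (mu[0] == 0 and mu[1] < 0):
        mu = -mu  # map onto the positive x half-plane
    phi = float(np.degrees(np.arctan2(mu[1], mu[0])))
    if phi <= -90.0:
        phi += 180.0
    th = np.deg2rad(phi)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return AlignmentResult(
        phi_deg=phi,
        applied=abs(phi) > gate_deg,
        mu=(float(mu[0]), float(mu[1])),
        rotation_matrix=rot,
    )


def align_image(
    slice_img: np.ndarray, result: AlignmentResult, fill: float = -1000.0
) -> np.ndarray:
    """Undo the estimated tilt (rotation about the image center).

    Returns the input unchanged when ``result.applied`` is false (tilt within
    the gate).  Bilinear interpolation; out-of-frame pixels get ``fill``.
    """
    img = np.asarray(slice_img, dtype=float)
    if img.size == 0:
        raise ValueError("empty slice")
    if not result.applied:
        return img
    # A bone axis with phi > 0 runs downward to the right; skimage's positive
    # (counter-clockwise) angle brings it back to horizontal.
    return transform.rotate(
        img,
        angle=result.phi_deg,
        resize=False,
        center=None,
        order=1,
        mode="constant",
        cval=float(fill),
        preserve_range=True,
    )


def otsu_threshold(slice_img: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold.

    Foreground convention: ``pixel > threshold``.  For images with few
    distinct values (piecewise-constant phantoms, 8-bit scans) the histogram
    is built on the exact values so the returned threshold is a data value
    and the split is exact; quasi-continuous images fall back to 256 uniform
    bins.
    """
    img = np.asarray(slice_img, dtype=float)
    vals, counts = np.unique(img, return_counts=True)
    if vals.size < 2:
        raise NoForeground("constant-intensity slice has no Otsu threshold")
    if vals.size <= 4096:
        return float(filters.threshold_otsu(hist=(counts, vals)))
    return float(filters.threshold_otsu(img, nbins=256))


def chest_mask(slice_img: np.ndarray, opening_radius: int = 3) -> np.ndarray:
    """Extract the chest (body) mask of one slice.

    Otsu binarization (foreground = above threshold), disk opening of radius
    ``opening_radius``, largest 8-connected component, hole filling.

    Raises
    ------
    NoForeground
        If binarization (or the subsequent opening) leaves no foreground.
    """
    img = np.asarray(slice_img, dtype=float)
    t = otsu_threshold(img)
    fg = img > t
    if not fg.any():
        raise NoForeground("Otsu binarization produced an empty foreground")
    if opening_radius > 0:
        fg = morphology.opening(fg, morphology.disk(opening_radius))
    if not fg.any():
        raise NoForeground("morphological opening removed all foreground")
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    return ndi.binary_fill_holes(fg)
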