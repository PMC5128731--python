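"""Shared fixtures: random blob masks, phantom outputs, pixel-chain shapes."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from lungtrace import phantom


def make_blob(seed: int, shape=(64, 64), quantile: float = 0.8) -> np.ndarray | None:
    """One smooth, hole-free, border-free blob mask, or None if the draw is
    unusable (multiple components after regularization, touches border,
    too small)."""
    rng = np.random.default_rng(seed)
    field = ndi.gaussian_filter(rng.normal(size=shape), 6)
    blob = field > np.quantile(field, quantile)
    eight = np.ones((3, 3), dtype=int)
    for _ in range(2):
        labels, n = ndi.label(blob, structure=eight)
        if n == 0:
            return None
        sizes = ndi.sum_labels(blob, labels, index=np.arange(1, n + 1))
        blob = labels == (int(np.argmax(sizes)) + 1)
        blob = ndi.binary_fill_holes(blob)
        blob = ndi.binary_opening(blob, structure=ndi.generate_binary_structure(2, 1))
    labels, n = ndi.label(blob, structure=eight)
    if n != 1:
        return None
    blob = ndi.binary_fill_holes(blob)
    if (
        blob[0].any()
        or blob[-1].any()
        or blob[:, 0].any()
        or blob[:, -1].any()
        or blob.sum() < 30
    ):
        return None
    return blob


def blob_series(count: int, start_seed: int = 0, **kw) -> list[np.ndarray]:
    blobs = []
    seed = start_seed
    while len(blobs) < count:
        b = make_blob(seed, **kw)
        seed += 1
        if b is not None:
            blobs.append(b)
    return blobs


def boundary_pixel_set(region: np.ndarray) -> set[tuple[int, int]]:
    """Oracle: region pixels with >= 1 background pixel in their
    8-neighborhood (array border counts as background)."""
    padded = np.pad(region, 1, constant_values=False)
    has_bg = ndi.maximum_filter(~padded, size=3)[1:-1, 1:-1]
    return set(zip(*np.nonzero(region & has_bg)))


def random_mask_3d(rng: np.random.Generator, max_side: int = 20) -> np.ndarray:
    """Small random non-empty 3D blob mask."""
    shape = tuple(int(rng.integers(6, max_side + 1)) for _ in range(3))
    field = ndi.gaussian_filter(rng.normal(size=shape), 2)
    mask = field > np.quantile(field, 0.75)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask


@pytest.fixture(scope="session")
def default_phantom():
    return phantom.generate_phantom(phantom.default_spec(noise_sd=20.0, seed=3))


@pytest.fixture(scope="session")
def fused_phantom():
    return phantom.generate_phantom(
        phantom.default_spec(fused_lungs=True, noise_sd=20.0, seed=7)
    )


@pytest.fixture(scope="session")
def nodule_phantom():
    spec = phantom.default_spec(
        nodules=(phantom.Nodule(lung=0, angle_deg=170, diameter_mm=12.0),),
        noise_sd=20.0,
        seed=5,
    )
    return phantom.generate_phantom(spec)


def staircase_circle_contour(radius: int, step: float = 0.3):
    """Resampled contour of a rasterized disk, traced as the classic Moore
    chain (diagonal shortcuts allowed, the natural 'staircase')."""
    from lungtrace import tracing
    from lungtrace.refinement import resample_contour

    size = 2 * radius + 20
    rr, cc = np.indices((size, size))
    disk = (rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= radius**2
    binary = (~disk).astype(np.uint8)
    rows, cols = np.nonzero(disk)
    contour = tracing.trace_border(
        binary, (rows[0], cols[0]), visit_inner_corners=False
    )
    return resample_contour(contour, step)
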