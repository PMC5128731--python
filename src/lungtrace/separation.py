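"""Left/right lung separation for slices where the lungs touch.

Near the anterior or posterior junction the thin tissue band between the
lungs can fall below the threshold, fusing both lungs into one connected
component.  Two strategies split it:

1. *Erosion + constrained reconstruction* (primary): erode with the
   4-neighbor diamond until the component splits, then grow the split parts
   back inside the original mask by conditional dilation that never merges
   components, leaving a one-pixel-wide cut.
2. *Maximum cost path* (fallback): dynamic programming finds the
   top-to-bottom path of maximal summed intensity inside a central column
   band — the bright junction tissue — and the mask is cut along it.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyBand, SeparationFailed, SplitFailed

__all__ = [
    "SeparationResult",
    "max_cost_path",
    "erode_until_split",
    "constrained_reconstruct",
    "separate_lungs",
]

_EIGHT = np.ones((3, 3), dtype=int)
_B4 = ndi.generate_binary_structure(2, 1)  # 4-neighbor diamond


@dataclass
class SeparationResult:
    left_mask: np.ndarray
    right_mask: np.ndarray
    erosion_iters: int = 0
    path: list[tuple[int, int]] = field(default_factory=list)
    method: str = "none_needed"  # none_needed | erosion | path


def max_cost_path(
    weights: np.ndarray, band: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """Top-to-bottom path of maximal summed weight.

    Each step moves one row down with column change in {-1, 0, +1},
    restricted to columns ``band = (c0, c1)`` (half-open).  Ties prefer the
    straight move, then the left one, and the leftmost final column, making
    the result deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("weights must be 2D with at least 2 rows")
    if band is None:
        band = (0, w.shape[1])
    c0, c1 = int(band[0]), int(band[1])
    c0 = max(c0, 0)
    c1 = min(c1, w.shape[1])
    if c1 <= c0:
        raise EmptyBand(f"band ({band[0]}, {band[1]}) is empty")
    sub = w[:, c0:c1]
    rows, ncol = sub.shape

    score = sub[0].copy()
    # choice[r, c]: predecessor column offset (-1, 0, +1) for row r
    choice = np.zeros((rows, ncol), dtype=np.int8)
    for r in range(1, rows):
        prev = score
        best = prev.copy()  # straight
        pick = np.zeros(ncol, dtype=np.int8)
        from_left = np.full(ncol, -np.inf)
        from_left[1:] = prev[:-1]
        better = from_left > best
        best[better] = from_left[better]
        pick[better] = -1
        from_right = np.full(ncol, -np.inf)
        from_right[:-1] = prev[1:]
        better = from_right > best
        best[better] = from_right[better]
        pick[better] = 1
        score = best + sub[r]
        choice[r] = pick

    c = int(np.argmax(score))  # argmax returns the leftmost maximum
    path = [(rows - 1, c)]
    for r in range(rows - 1, 0, -1):
        c = c + int(choice[r, c])
        path.append((r - 1, c))
    path.reverse()
    return [(r, c + c0) for r, c in path]


def erode_until_split(
    mask: np.ndarray, max_iters: int = 20
) -> tuple[np.ndarray, int]:
    """Erode with the diamond ``B4`` until the 8-connected component count
    reaches two or more; returns the eroded mask and the iteration count.

    Raises
    ------
    SplitFailed
        If the mask vanishes, or ``max_iters`` erosions do not split it.
    """
    s = np.asarray(mask, dtype=bool)
    _, n0 = ndi.label(s, structure=_EIGHT)
    if n0 != 1:
        raise ValueError("erode_until_split requires exactly one component")
    for it in range(1, max_iters + 1):
        s = ndi.binary_erosion(s, structure=_B4, border_value=0)
        if not s.any():
            raise SplitFailed(f"mask vanished at erosion {it} without splitting")
        _, n = ndi.label(s, structure=_EIGHT)
        if n >= 2:
            return s, it
    raise SplitFailed(f"no split after {max_iters} erosions")


def constrained_reconstruct(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Grow ``seed`` back inside ``mask`` without merging components.

    Conditional dilation with the diamond ``B4``: pixels of ``mask`` are
    claimed one at a time (FIFO over the dilation frontier) and accepted
    only when exactly one seed component appears in their 8-neighborhood;
    pixels touching two components are permanently blocked, which leaves
    the one-pixel-wide cut.  Idempotent: feeding the output back in
    returns it unchanged.
    """
    seed = np.asarray(seed, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if (seed & ~mask).any():
        raise ValueError("seed must be a subset of mask")
    labels, n = ndi.label(seed, structure=_EIGHT)
    labels = labels.astype(np.int32)
    rows, cols = mask.shape
    BLOCKED = -1
    queue: deque[tuple[int, int]] = deque()
    queued = np.zeros_like(mask, dtype=bool)

    def push_neighbors(r: int, c: int) -> None:
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if (
                0 <= rr < rows
                and 0 <= cc < cols
                and mask[rr, cc]
                and labels[rr, cc] == 0
                and not queued[rr, cc]
            ):
                queued[rr, cc] = True
                queue.append((rr, cc))

    for r, c in zip(*np.nonzero(seed)):
        push_neighbors(int(r), int(c))

    while queue:
        r, c = queue.popleft()
        queued[r, c] = False
        if labels[r, c] != 0:
            continue
        neigh = labels[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        vals = np.unique(neigh[neigh > 0])
        if vals.size == 1:
            labels[r, c] = vals[0]
            push_neighbors(r, c)
        elif vals.size >= 2:
            labels[r, c] = BLOCKED
        # vals.size == 0: stale entry; a later neighbor assignment re-queues

    return labels > 0


def separate_lungs(
    lung_mask: np.ndarray,
    intensity_slice: np.ndarray | None = None,
    max_iters: int = 20,
    band_fraction: float = 1.0 / 3.0,
) -> SeparationResult:
    """Split a lung mask into disjoint left and right masks.

    With two or more components the two largest are labeled by centroid
    column (``none_needed``).  A single component is split by erosion +
    constrained reconstruction; if that fails and ``intensity_slice`` is
    given, the mask is cut along the maximum cost path of the intensity
    inside the central ``band_fraction`` of its bounding-box columns.

    Raises
    ------
    SeparationFailed
        If the mask is empty or no strategy yields two components.
    """
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise SeparationFailed("empty lung mask")
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n >= 2:
        left, right = _two_largest_by_column(labels, n)
        return SeparationResult(left, right, method="none_needed")

    try:
        s, iters = erode_until_split(mask, max_iters=max_iters)
        rebuilt = constrained_reconstruct(s, mask)
        labels, n = ndi.label(rebuilt, structure=_EIGHT)
        if n >= 2:
            left, right = _two_largest_by_column(labels, n)
            return SeparationResult(
                left, right, erosion_iters=iters, method="erosion"
            )
    except SplitFailed:
        pass

    if intensity_slice is not None:
        cols = np.nonzero(mask.any(axis=0))[0]
        c_lo, c_hi = cols[0], cols[-1] + 1
        width = c_hi - c_lo
        pad = (1.0 - band_fraction) / 2.0
        band = (c_lo + int(pad * width), c_hi - int(pad * width))
        w = np.asarray(intensity_slice, dtype=float)
        w = w - w.min()
        path = max_cost_path(w, band=band)
        cut = mask.copy()
        prev_c = None
        for r, c in path:
            cut[r, c] = False
            # a diagonal path step leaves an 8-connected leak; widen the cut
            if prev_c is not None and c != prev_c:
                cut[r, prev_c] = False
            prev_c = c
        labels, n = ndi.label(cut, structure=_EIGHT)
        if n >= 2:
            left, right = _two_largest_by_column(labels, n)
            return SeparationResult(left, right, path=path, method="path")

    raise SeparationFailed("all separation strategies failed")


def _two_largest_by_column(
    labels: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    sizes = ndi.sum_labels(labels > 0, labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:2] + 1
    masks = [labels == k for k in order]
    cols = [np.nonzero(m.any(axis=0))[0].mean() for m in masks]
    if cols[0] <= cols[1]:
        return masks[0], masks[1]
    return masks[1], masks[0]
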