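"""Lung contour initialization by diagonal search and Moore border tracing.

The slice is binarized *within the chest*: lung (air-density) pixels are 0,
tissue pixels are 1, and everything outside the chest mask is forced to 1 so
the diagonal scan cannot trigger on background air.  Scanning along the
major diagonal (top-left to bottom-right) the first run of at least three
consecutive 0s encountered after some tissue marks the entry into the
image-left lung; the minor diagonal (top-right to bottom-left) finds the
image-right lung.  From each start the region border is walked with
Moore-neighbor (8-neighborhood) tracing, stopping with Jacob's criterion:
the walk ends when the last two visited pixels repeat the first two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OpenContour, StartNotFound
from .preprocess import otsu_threshold

__all__ = [
    "Contour",
    "binarize_within_chest",
    "find_diagonal_start",
    "trace_border",
    "extract_lung_contours",
]

# Moore neighborhood in clockwise display order starting north.
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_OFFSET_TO_DIR = {off: i for i, off in enumerate(_MOORE)}


@dataclass
class Contour:
    """Ordered, closed, 8-connected pixel boundary of one lung."""

    points: list[tuple[int, int]]  # (row, col)
    closed: bool = True
    side: str = "unknown"  # left | right | unknown

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)

    def point_set(self) -> set[tuple[int, int]]:
        return set(self.points)


def binarize_within_chest(
    slice_img: np.ndarray,
    chest: np.ndarray,
    threshold: float | None = None,
) -> np.ndarray:
    """Binarize a slice for lung tracing: 0 = lung air, 1 = tissue/outside.

    ``threshold`` defaults to the slice's Otsu threshold (the same one the
    chest mask was built from).
    """
    img = np.asarray(slice_img, dtype=float)
    chest = np.asarray(chest, dtype=bool)
    if threshold is None:
        threshold = otsu_threshold(img)
    binary = (img > threshold).astype(np.uint8)
    binary[~chest] = 1
    return binary


def _diagonal_indices(
    shape: tuple[int, int], diagonal: str, offset: int = 0
) -> list[tuple[int, int]]:
    rows, cols = shape
    pts = []
    if diagonal == "major":  # top-left -> bottom-right; offset shifts columns
        for i in range(rows):
            j = i + offset
            if 0 <= j < cols:
                pts.append((i, j))
    elif diagonal == "minor":  # top-right -> bottom-left
        for i in range(rows):
            j = cols - 1 - i + offset
            if 0 <= j < cols:
                pts.append((i, j))
    else:
        raise ValueError("diagonal must be 'major' or 'minor'")
    return pts


def find_diagonal_start(
    binary_slice: np.ndarray,
    diagonal: str,
    offset: int = 0,
    min_run: int = 3,
) -> tuple[int, int]:
    """First pixel starting a run of >= ``min_run`` 0s on the diagonal.

    The run must come after at least one 1 so the search has crossed chest
    tissue before declaring a lung entry.

    Raises
    ------
    StartNotFound
        If no qualifying run exists on this diagonal.
    """
    binary = np.asarray(binary_slice)
    path = _diagonal_indices(binary.shape, diagonal, offset)
    seen_tissue = False
    run_start = None
    run_len = 0
    for rc in path:
        v = binary[rc]
        if v:
            seen_tissue = True
            run_start, run_len = None, 0
        elif seen_tissue:
            if run_start is None:
                run_start, run_len = rc, 1
            else:
                run_len += 1
            if run_len >= min_run:
                return run_start
    raise StartNotFound(f"no run of {min_run} lung pixels on {diagonal} diagonal")


def _initial_backtrack(
    binary: np.ndarray, start: tuple[int, int]
) -> tuple[int, int]:
    """A 1-neighbor of ``start`` to seed the Moore walk (prefer north)."""
    rows, cols = binary.shape
    for dr, dc in _MOORE:
        r, c = start[0] + dr, start[1] + dc
        if not (0 <= r < rows and 0 <= c < cols) or binary[r, c]:
            return (start[0] + dr, start[1] + dc)
    raise ValueError("start pixel has no tissue neighbor; not a boundary pixel")


def trace_border(
    binary_slice: np.ndarray,
    start: tuple[int, int],
    backtrack: tuple[int, int] | None = None,
    step_budget: int | None = None,
    visit_inner_corners: bool = True,
) -> Contour:
    """Moore-neighbor trace of the 0-region boundary containing ``start``.

    Walks clockwise, examining the 8 neighbors of the current pixel starting
    just past the backtrack position; terminates via Jacob's criterion
    (P_n = P_2 and P_{n-1} = P_1), trimming the duplicate pair.

    With ``visit_inner_corners`` (default) a diagonal move also visits the
    intervening 4-neighbor region pixel, so the contour covers *every*
    region pixel that has a background pixel in its 8-neighborhood — pixels
    on the inside of a diagonal staircase included.  Without it the walk is
    the classic Moore chain (diagonal shortcuts allowed).

    Raises
    ------
    OpenContour
        If the walk exceeds ``step_budget`` (default 4x the slice
        perimeter) without closing.
    """
    binary = np.asarray(binary_slice)
    rows, cols = binary.shape
    start = (int(start[0]), int(start[1]))
    if binary[start]:
        raise ValueError("start must be a lung (0) pixel")
    if backtrack is None:
        backtrack = _initial_backtrack(binary, start)
    if step_budget is None:
        step_budget = 4 * 2 * (rows + cols)

    def is_region(r: int, c: int) -> bool:
        return 0 <= r < rows and 0 <= c < cols and not binary[r, c]

    points = [start]
    cur = start
    back = backtrack
    back0 = backtrack
    steps = 0
    while steps < step_budget:
        if steps > 0 and cur == start and back == back0:
            # full cycle: the walk state repeats its initial configuration
            return _dedupe(points[:-1])
        d = _OFFSET_TO_DIR[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        ring_idx = 0
        for k in range(1, 9):
            ring_idx = (d + k) % 8
            dr, dc = _MOORE[ring_idx]
            cand = (cur[0] + dr, cur[1] + dc)
            if is_region(*cand):
                nxt = cand
                break
            back = cand
        if nxt is None:
            # isolated single pixel: closed by convention
            return Contour(points=[start], closed=True)
        new_points = [nxt]
        if visit_inner_corners and ring_idx % 2 == 1:
            # Diagonal move: also visit the inner-corner pixel shared with
            # the next clockwise 4-neighbor, so the walk never cuts a corner
            # and covers pixels whose only background contact is diagonal.
            pr, pc = _MOORE[(ring_idx + 1) % 8]
            inner = (cur[0] + pr, cur[1] + pc)
            if is_region(*inner):
                new_points = [inner, nxt]
        for p in new_points:
            points.append(p)
            steps += 1
            n = len(points)
            if n >= 4 and points[-1] == points[1] and points[-2] == points[0]:
                return _dedupe(points[:-2])
        cur = nxt
    raise OpenContour(f"tracing exceeded {step_budget} steps without closing")


def _dedupe(points: list[tuple[int, int]]) -> Contour:
    """Drop repeat visits (inner corners crossed twice) when removal keeps
    consecutive points 8-adjacent; then wrap into a closed contour."""
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n = len(points)
    for i, p in enumerate(points):
        if p in seen:
            prev = out[-1]
            nxt = points[(i + 1) % n]
            if max(abs(prev[0] - nxt[0]), abs(prev[1] - nxt[1])) <= 1:
                continue
        out.append(p)
        seen.add(p)
    return Contour(points=out, closed=True)


def extract_lung_contours(
    binary_slice: np.ndarray,
    max_offset: int | None = None,
) -> tuple[Contour | None, Contour | None]:
    """Trace the image-left and image-right lung contours of one slice.

    The left contour starts from the major-diagonal entry, the right from
    the minor-diagonal entry; if the geometric diagonal misses a lung the
    scan falls back to parallel diagonals offset by +-1, +-2, ... px.  A
    side with no start at all is returned as ``None``; when both starts fall
    in the same 0-component the two contours have identical point sets and
    the caller should run lung separation.

    Raises
    ------
    StartNotFound
        Only when *both* diagonals fail (a slice with no lungs).
    """
    binary = np.asarray(binary_slice)
    if max_offset is None:
        max_offset = min(binary.shape) // 2

    def find_side(diagonal: str) -> Contour | None:
        for k in range(max_offset + 1):
            for off in ((k,) if k == 0 else (k, -k)):
                try:
                    start = find_diagonal_start(binary, diagonal, offset=off)
                except StartNotFound:
                    continue
                return trace_border(binary, start)
        return None

    left = find_side("major")
    right = find_side("minor")
    if left is None and right is None:
        raise StartNotFound("no lung entry on either diagonal")
    if left is not None:
        left.side = "left"
    if right is not None:
        right.side = "right"
    return left, right


def contour_to_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Filled pixel mask of a traced contour (scan fill of the polygon,
    boundary pixels included)."""
    from scipy import ndimage as ndi

    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(contour.points, dtype=int)
    mask[pts[:, 0], pts[:, 1]] = True
    return ndi.binary_fill_holes(mask)
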