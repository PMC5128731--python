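"""Contour refinement: arc-length smoothing and concave-region correction.

The traced lung border is a jagged pixel chain.  It is first resampled to a
closed cubic-spline curve with uniform arc-length spacing ``L`` (default
0.3 px), then smoothed by sliding least-squares polynomial fits: around each
point a degree-``n`` polynomial in the arc abscissa is fitted to the
``2k + 1`` window points (abscissae 0, L, ..., 2kL) and the point is
replaced by the fitted value at the window center ``kL``.  Passes repeat
until the perimeter change drops below a tolerance ``T2`` or a pass budget
``M`` is exhausted.  With uniform abscissae the per-window least-squares fit
reduces to a fixed convolution kernel (the projection row of the Vandermonde
system at ``s = kL``), applied cyclically.

Density-based thresholding excludes juxta-pleural nodules from the lung, so
the smoothed parenchyma border carries concave notches at the pleural wall.
A border march with the right-hand rule (a monotone convex-chain sweep over
the clockwise contour: advance while the next point lies to the right of
the current direction, pop otherwise) finds each concave region and its
bridging chord; regions whose depth-to-width ratio ``eta = H / W`` exceeds a
threshold ``T1`` are replaced by the straight chord, re-including the
nodule.  The detect/replace cycle repeats until the perimeter converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import convolve1d, gaussian_filter1d
from skimage.draw import polygon2mask

from .errors import DegenerateContour, IllConditionedFit, NonConvergence
from .tracing import Contour

__all__ = [
    "SmoothingParams",
    "ConcaveRegion",
    "FloatContour",
    "resample_contour",
    "smooth_contour",
    "detect_concaves",
    "correct_contour",
    "rasterize",
    "signed_area",
    "enclosed_area",
    "ensure_clockwise",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Arc-length smoothing parameters.

    ``poly_degree`` (n) and ``half_window`` (k) define the local fit
    (``2k > n`` required); ``max_passes`` (M) bounds the smoothing passes;
    ``step`` (L, pixels) is the resampling arc spacing; ``perimeter_tol``
    (T2, pixels) is the convergence tolerance on the perimeter change.
    """

    poly_degree: int = 2
    half_window: int = 4
    max_passes: int = 12
    step: float = 0.3
    perimeter_tol: float = 0.01

    def __post_init__(self) -> None:
        if 2 * self.half_window <= self.poly_degree:
            raise ValueError("need 2 * half_window > poly_degree")
        if self.step <= 0 or self.perimeter_tol <= 0:
            raise ValueError("step and perimeter_tol must be positive")


@dataclass(frozen=True)
class ConcaveRegion:
    """A concave indentation: chord endpoints (indices into the contour),
    chord width W, maximum perpendicular depth H, and ratio eta = H / W."""

    start_idx: int
    end_idx: int
    W: float
    H: float
    eta: float


@dataclass
class FloatContour:
    """Closed sub-pixel contour: (row, col) float points at ~uniform arc
    spacing ``step``."""

    points: np.ndarray  # (N, 2) float, (row, col)
    step: float
    side: str = "unknown"
    n_passes: int = 0
    converged: bool = True
    n_corrected: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area with x = col, y = row (y increasing downward);
    positive for clockwise traversal in the displayed image."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 1], p[:, 0]
    return 0.5 * float(
        np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    )


def enclosed_area(curve: FloatContour | np.ndarray) -> float:
    pts = curve.points if isinstance(curve, FloatContour) else curve
    return abs(signed_area(pts))


def ensure_clockwise(curve: FloatContour) -> FloatContour:
    """Return the curve oriented clockwise (interior to the right of travel)."""
    if signed_area(curve.points) >= 0:
        return curve
    return dc_replace(curve, points=curve.points[::-1].copy())


# ---------------------------------------------------------------------------
# resampling

def resample_contour(contour: Contour, step: float = 0.3) -> FloatContour:
    """Closed periodic cubic-spline resampling at uniform arc length.

    The output has ``round(perimeter / step)`` points; the actual spacing is
    ``perimeter / count`` so the closure gap equals the spacing exactly.

    Raises
    ------
    DegenerateContour
        For contours of fewer than 10 points or ``step >= perimeter / 4``.
    """
    pts = contour.as_array()
    if len(pts) < 10:
        raise DegenerateContour(f"contour has {len(pts)} points (< 10)")
    closed = np.vstack([pts, pts[:1]])
    chord = np.hypot(*np.diff(closed, axis=0).T)
    if (chord == 0).any():
        keep = np.concatenate([[True], chord > 0])
        closed = closed[keep]
        chord = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    total = t[-1]
    if step >= total / 4:
        raise DegenerateContour(f"step {step} >= perimeter/4 = {total / 4}")
    spline = CubicSpline(t, closed, bc_type="periodic", axis=0)

    # invert arc length on a dense polyline of the spline
    t_dense = np.linspace(0.0, total, max(8 * len(pts), 512))
    dense = spline(t_dense)
    seg = np.hypot(*np.diff(dense, axis=0).T)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    arc_total = s_dense[-1]
    count = int(round(arc_total / step))
    s_targets = np.arange(count) * (arc_total / count)
    t_targets = np.interp(s_targets, s_dense, t_dense)
    return FloatContour(
        points=spline(t_targets), step=arc_total / count, side=contour.side
    )


# ---------------------------------------------------------------------------
# smoothing

def _center_fit_kernel(poly_degree: int, half_window: int) -> np.ndarray:
    """Convolution weights giving the least-squares polynomial fit value at
    the center of a ``2k + 1`` window with uniform abscissae."""
    k = half_window
    s = np.arange(2 * k + 1, dtype=float)  # L cancels out of the projection
    A = np.vander(s, poly_degree + 1, increasing=True)
    try:
        proj = A @ np.linalg.pinv(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - fixed abscissae
        raise IllConditionedFit(str(exc)) from exc
    return proj[k]


def smooth_contour(
    curve: FloatContour, params: SmoothingParams = SmoothingParams()
) -> FloatContour:
    """Iterative sliding-window least-squares smoothing of a closed curve.

    Each pass replaces every point by the degree-``n`` fit over its
    ``2k + 1`` cyclic neighbors evaluated at the window center; passes stop
    when the perimeter changes by less than ``perimeter_tol`` or after
    ``max_passes`` passes.  Points exactly on a straight line or on a
    degree-``n`` polynomial arc are reproduced exactly.
    """
    pts = np.asarray(curve.points, dtype=float)
    if len(pts) <= 2 * params.half_window + 1:
        return dc_replace(curve, n_passes=0, converged=True)
    weights = _center_fit_kernel(params.poly_degree, params.half_window)

    prev_perim = FloatContour(pts, curve.step).perimeter
    converged = False
    n_passes = 0
    for _ in range(params.max_passes):
        pts = np.column_stack(
            [convolve1d(pts[:, j], weights, mode="wrap") for j in (0, 1)]
        )
        n_passes += 1
        perim = FloatContour(pts, curve.step).perimeter
        if abs(perim - prev_perim) < params.perimeter_tol:
            converged = True
            prev_perim = perim
            break
        prev_perim = perim
    return dc_replace(
        curve, points=pts, n_passes=n_passes, converged=converged
    )


# ---------------------------------------------------------------------------
# concave detection and correction

_H_EPS = 1e-7


def detect_concaves(
    curve: FloatContour, march_step: int = 5, detect_sigma: float = 2.0
) -> list[ConcaveRegion]:
    """March the closed contour and report its concave regions.

    The contour is swept clockwise starting from a point guaranteed to be
    convex (the topmost point).  A chord chain is extended while each next
    point lies to the right of the current chord direction (right-hand
    rule); when points fall to the left the chain pops, so chain vertices
    are exactly the locally convex anchors and every skipped stretch is a
    concave region.  A region spanning fewer than ``march_step`` contour
    points is ignored as sampling noise.  Indices in the result refer to
    ``curve.points`` in its given order.

    The chain itself is built on a copy of the contour low-pass filtered
    along arc length with ``detect_sigma`` (px): residual raster ripple
    otherwise breaks one deep indentation into a sprawl of shallow pockets
    whose bridging chords overshoot the mouth.  Chord endpoints, widths and
    depths are always measured on the *original* points, with the endpoints
    snapped to the indentation mouth, so constructed geometry is reported
    exactly.
    """
    pts = np.asarray(curve.points, dtype=float)
    n = len(pts)
    if n < 4:
        return []
    reversed_input = signed_area(pts) < 0
    work = pts[::-1] if reversed_input else pts

    if detect_sigma > 0 and n > 8:
        sigma_idx = detect_sigma / max(curve.step, 1e-9)
        ghost = np.column_stack(
            [gaussian_filter1d(work[:, j], sigma_idx, mode="wrap") for j in (0, 1)]
        )
    else:
        ghost = work

    start = int(np.lexsort((ghost[:, 1], ghost[:, 0]))[0])  # topmost, then leftmost
    order = (np.arange(n + 1) + start) % n  # wraps back to the start point
    p = work[order]
    pg = ghost[order]

    stack = [0]
    for i in range(1, n + 1):
        while len(stack) >= 2:
            a, b = pg[stack[-2]], pg[stack[-1]]
            # right turn (clockwise, convex) has positive z with y downward
            cross = (b[1] - a[1]) * (pg[i][0] - b[0]) - (b[0] - a[0]) * (
                pg[i][1] - b[1]
            )
            # pop only on strictly concave (left) turns: collinear points
            # stay, so chord endpoints are the true region mouth, not the
            # far vertices of a straight hull edge
            if cross < -1e-12:
                stack.pop()
            else:
                break
        stack.append(i)

    regions: list[ConcaveRegion] = []
    for u, v in zip(stack[:-1], stack[1:]):
        if v - u < 2 or (v - u - 1) < march_step:
            continue
        trimmed = _trim_to_mouth(p, u, v)
        if trimmed is None:
            continue
        u, v, W, H = trimmed
        if (v - u - 1) < march_step or H <= _H_EPS:
            continue
        iu, iv = int(order[u]), int(order[v])
        if reversed_input:
            iu, iv = n - 1 - iv, n - 1 - iu
        regions.append(ConcaveRegion(iu, iv, W=W, H=H, eta=H / W))
    return regions


#: Points closer than this (px) to the bridging chord belong to its mouth,
#: not to the indentation proper; raster-scale ripple sits below it.
_MOUTH_TOL = 1.0


def _chord_depths(p: np.ndarray, u: int, v: int) -> tuple[float, np.ndarray] | None:
    A, B = p[u], p[v]
    chord = B - A
    W = float(np.hypot(*chord))
    if W == 0:
        return None
    d = np.abs(
        chord[1] * (p[u + 1 : v, 0] - A[0]) - chord[0] * (p[u + 1 : v, 1] - A[1])
    ) / W
    return W, d


def _trim_to_mouth(p: np.ndarray, u: int, v: int) -> tuple[int, int, float, float] | None:
    """Snap a concave region's chord endpoints to its mouth.

    On a curved (convex) boundary the chain chord overshoots the true
    indentation mouth: the contact points land where the boundary tangent
    turns parallel to the chord, several pixels beyond the opening, and
    thin parenchyma tongues flanking a notch push them further out.  The
    mouth is recovered from the depth profile: starting at the deepest
    point, walk outward in both directions until the perpendicular depth
    first falls below ``max(_MOUTH_TOL, 0.1 * depth)``; those crossings
    bound the indentation proper.  The chord is recomputed once on the
    trimmed endpoints.  Returns ``None`` for regions that are shallow
    ripple throughout.
    """
    res = _chord_depths(p, u, v)
    if res is None:
        return None
    _, d = res
    if d.size == 0:
        return None
    tau = _MOUTH_TOL
    m = int(np.argmax(d))  # d[j] is the depth of point u + 1 + j
    if d[m] < tau:
        return None
    j = m
    while j > 0 and d[j - 1] >= tau:
        j -= 1
    # continue down the strict descent to the local depth minimum: the
    # mouth corner (or tongue tip), so the bridge sits on the boundary line
    jj = j - 1
    while jj > 0 and d[jj - 1] < d[jj]:
        jj -= 1
    u2 = u + 1 + jj if jj >= 0 else u
    k = m
    while k < d.size - 1 and d[k + 1] >= tau:
        k += 1
    kk = k + 1
    while kk < d.size - 1 and d[kk + 1] < d[kk]:
        kk += 1
    v2 = u + 1 + kk if kk < d.size else v
    if v2 - u2 < 2:
        return None
    res = _chord_depths(p, u2, v2)
    if res is None:
        return None
    W, d = res
    if d.size == 0:
        return None
    return u2, v2, W, float(d.max())


def _chord_points(A: np.ndarray, B: np.ndarray, step: float) -> np.ndarray:
    """Interior points of segment A-B at ~``step`` spacing (endpoints excluded)."""
    length = float(np.hypot(*(B - A)))
    m = max(int(round(length / step)), 1)
    ts = np.arange(1, m) / m
    return A[None, :] + ts[:, None] * (B - A)[None, :]


def correct_contour(
    curve: FloatContour,
    ratio_threshold: float = 0.6,
    perimeter_tol: float = 0.01,
    march_step: int = 5,
    max_iters: int = 100,
) -> FloatContour:
    """Replace deep concave regions by straight chords until convergence.

    Each iteration detects concave regions and substitutes the arc of every
    region with ``eta > ratio_threshold`` (T1) by its chord, sampled at the
    curve's arc spacing; iterations stop when the perimeter change is below
    ``perimeter_tol`` (T2).  The enclosed area never decreases, since every
    replaced arc dips inside its bridging chord.

    Raises
    ------
    NonConvergence
        If the perimeter has not converged after ``max_iters`` iterations.
    """
    work = ensure_clockwise(curve)
    total_corrected = 0
    perim = work.perimeter
    for _ in range(max_iters):
        # roll so index 0 is the march start (topmost point, which is on the
        # convex chain); regions are then monotone, non-overlapping index
        # ranges and chord replacement is a simple splice
        pts = work.points
        n = len(pts)
        start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
        pts = np.roll(pts, -start, axis=0)
        work = dc_replace(work, points=pts)
        regions = [
            r
            for r in detect_concaves(work, march_step=march_step)
            if r.eta > ratio_threshold
        ]
        if not regions:
            return dc_replace(
                work, n_corrected=curve.n_corrected + total_corrected
            )
        regions.sort(key=lambda r: r.start_idx)
        pieces: list[np.ndarray] = []
        cursor = 0
        for r in regions:
            s = r.start_idx
            e = r.end_idx if r.end_idx > 0 else n  # wrap back to the start
            pieces.append(pts[cursor : s + 1])
            pieces.append(_chord_points(pts[s], pts[e % n], work.step))
            cursor = e
        if cursor < n:
            pieces.append(pts[cursor:])
        new_pts = np.vstack(pieces)
        total_corrected += len(regions)
        work = dc_replace(work, points=new_pts)
        new_perim = work.perimeter
        if abs(new_perim - perim) < perimeter_tol:
            return dc_replace(
                work, n_corrected=curve.n_corrected + total_corrected
            )
        perim = new_perim
    raise NonConvergence(f"perimeter not converged after {max_iters} iterations")


def rasterize(curve: FloatContour, shape: tuple[int, int]) -> np.ndarray:
    """Scan-fill the closed curve: pixels whose centers fall inside (or on)
    the polygon are set.  Orientation-independent."""
    return polygon2mask(shape, curve.points)
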