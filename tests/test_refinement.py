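"""Contour resampling, arc-length smoothing, concave detection/correction,
rasterization."""

import numpy as np
import pytest

from lungtrace import tracing
from lungtrace.errors import DegenerateContour
from lungtrace.refinement import (
    FloatContour,
    SmoothingParams,
    correct_contour,
    detect_concaves,
    enclosed_area,
    ensure_clockwise,
    rasterize,
    resample_contour,
    signed_area,
    smooth_contour,
)
from lungtrace.tracing import Contour

from conftest import staircase_circle_contour


def square_contour(side: int = 10, origin: int = 5) -> Contour:
    """Pixel chain around a square block of `side` x `side` zeros."""
    binary = np.ones((side + 2 * origin, side + 2 * origin), dtype=np.uint8)
    binary[origin : origin + side, origin : origin + side] = 0
    return tracing.trace_border(binary, (origin, origin))


def notched_rectangle(step: float = 1.0) -> FloatContour:
    """20x30 rectangle with a width-4, depth-10 notch in its top edge,
    clockwise, unit point spacing."""
    pts = []
    pts += [(0, c) for c in range(0, 14)]
    pts += [(r, 13) for r in range(1, 11)]
    pts += [(10, c) for c in range(14, 17)]
    pts += [(r, 17) for r in range(9, -1, -1)]
    pts += [(0, c) for c in range(18, 31)]
    pts += [(r, 30) for r in range(1, 21)]
    pts += [(20, c) for c in range(29, -1, -1)]
    pts += [(r, 0) for r in range(19, 0, -1)]
    return FloatContour(np.array(pts, dtype=float), step=step)


class TestResample:
    def test_square_resamples_to_uniform_spacing(self):
        contour = square_contour(side=10)
        fc = resample_contour(contour, step=0.5)
        # 10x10 pixel block -> 9x9 boundary square, perimeter 36
        assert len(fc) == round(fc.perimeter / 0.5) == pytest.approx(72, abs=1)
        closed = np.vstack([fc.points, fc.points[:1]])
        gaps = np.hypot(*np.diff(closed, axis=0).T)
        assert gaps == pytest.approx(0.5, abs=0.02)

    def test_too_few_points_raises(self):
        contour = Contour(points=[(0, 0), (0, 1), (1, 1)], closed=True)
        with pytest.raises(DegenerateContour):
            resample_contour(contour, 0.3)

    def test_step_too_coarse_raises(self):
        with pytest.raises(DegenerateContour):
            resample_contour(square_contour(side=10), step=15.0)

    def test_circle_length_preserved_within_one_percent(self):
        fc = staircase_circle_contour(20, step=0.3)
        rr, cc = np.indices((60, 60))
        disk = (rr - 30) ** 2 + (cc - 30) ** 2 <= 400
        binary = (~disk).astype(np.uint8)
        rows, cols = np.nonzero(disk)
        chain = tracing.trace_border(
            binary, (rows[0], cols[0]), visit_inner_corners=False
        )
        chain_perimeter = FloatContour(
            np.asarray(chain.points, dtype=float), 1.0
        ).perimeter
        assert fc.perimeter == pytest.approx(chain_perimeter, rel=0.01)


class TestSmoothing:
    def test_straight_edge_points_are_reproduced_exactly(self):
        rect = notched_rectangle()
        # use an un-notched rectangle: long straight edges
        pts = []
        pts += [(0, c) for c in range(0, 31)]
        pts += [(r, 30) for r in range(1, 21)]
        pts += [(20, c) for c in range(29, -1, -1)]
        pts += [(r, 0) for r in range(19, 0, -1)]
        curve = FloatContour(np.array(pts, dtype=float), step=1.0)
        smoothed = smooth_contour(curve, SmoothingParams(max_passes=1, step=1.0))
        # points >= k away from any corner sit in all-linear windows
        k = 4
        for idx in range(k + 1, 31 - k - 1):  # interior of the top edge
            assert smoothed.points[idx] == pytest.approx(curve.points[idx], abs=1e-9)
        assert rect is not None

    def test_parabola_arc_is_reproduced_by_quadratic_fit(self):
        # quadratic fit in the arc abscissa reproduces data sampled from a
        # quadratic exactly; check the kernel on a synthetic window
        from lungtrace.refinement import _center_fit_kernel

        w = _center_fit_kernel(2, 4)
        s = np.arange(9, dtype=float)
        y = 3.0 - 0.5 * s + 0.25 * s**2
        assert float(w @ y) == pytest.approx(y[4], abs=1e-9)

    @pytest.mark.parametrize("radius", [20, 30])
    def test_staircase_circle_perimeter_contracts_each_pass(self, radius):
        fc = staircase_circle_contour(radius)
        perims = [fc.perimeter]
        cur = fc
        for _ in range(8):
            cur = smooth_contour(cur, SmoothingParams(max_passes=1))
            perims.append(cur.perimeter)
        assert all(b <= a + 1e-9 for a, b in zip(perims, perims[1:]))

    def test_converges_to_circle_circumference(self):
        fc = staircase_circle_contour(30)
        smoothed = smooth_contour(fc, SmoothingParams(max_passes=100))
        assert smoothed.converged
        assert smoothed.perimeter == pytest.approx(2 * np.pi * 30, rel=0.02)

    def test_short_curve_returned_unchanged(self):
        curve = FloatContour(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]]), 1.0)
        out = smooth_contour(curve)
        assert np.array_equal(out.points, curve.points)


class TestDetectConcaves:
    def test_convex_hexagon_has_no_concave_regions(self):
        angles = np.linspace(0, 2 * np.pi, 7)[:-1]
        pts = np.column_stack([10 - 8 * np.sin(angles), 10 + 8 * np.cos(angles)])
        curve = FloatContour(pts, step=1.0)
        assert detect_concaves(curve, march_step=1) == []

    def test_rectangular_notch_measured_exactly(self):
        regions = detect_concaves(notched_rectangle(), march_step=1)
        assert len(regions) == 1
        region = regions[0]
        assert region.W == pytest.approx(4.0, abs=1e-9)
        assert region.H == pytest.approx(10.0, abs=1e-9)
        assert region.eta == pytest.approx(2.5, abs=1e-9)

    def test_two_disjoint_notches_give_two_regions(self):
        pts = []
        pts += [(0, c) for c in range(0, 6)]
        pts += [(r, 5) for r in range(1, 7)] + [(6, 6)] + [(r, 7) for r in range(5, -1, -1)]
        pts += [(0, c) for c in range(8, 20)]
        pts += [(r, 19) for r in range(1, 9)] + [(8, 20)] + [(r, 21) for r in range(7, -1, -1)]
        pts += [(0, c) for c in range(22, 31)]
        pts += [(r, 30) for r in range(1, 16)]
        pts += [(15, c) for c in range(29, -1, -1)]
        pts += [(r, 0) for r in range(14, 0, -1)]
        curve = FloatContour(np.array(pts, dtype=float), step=1.0)
        regions = detect_concaves(curve, march_step=1)
        assert len(regions) == 2
        spans = sorted((r.start_idx, r.end_idx) for r in regions)
        assert spans[0][1] <= spans[1][0]  # non-overlapping index ranges

    def test_counterclockwise_input_gives_same_measurements(self):
        cw = notched_rectangle()
        ccw = FloatContour(cw.points[::-1].copy(), step=1.0)
        r_cw = detect_concaves(cw, march_step=1)[0]
        r_ccw = detect_concaves(ccw, march_step=1)[0]
        assert r_ccw.W == pytest.approx(r_cw.W)
        assert r_ccw.H == pytest.approx(r_cw.H)


class TestCorrectContour:
    def test_notch_replaced_by_chord_increases_area_by_notch_area(self):
        curve = notched_rectangle()
        corrected = correct_contour(curve, ratio_threshold=1.0, march_step=1)
        gain = enclosed_area(corrected) - enclosed_area(curve)
        assert gain == pytest.approx(40.0, abs=1.0)  # 4 x 10 notch
        assert corrected.n_corrected >= 1

    def test_shallow_dent_left_unchanged(self):
        pts = []
        pts += [(0, c) for c in range(0, 13)]
        pts += [(2, c) for c in range(13, 18)]  # wide shallow dent, eta = 2/5
        pts += [(0, c) for c in range(18, 31)]
        pts += [(r, 30) for r in range(1, 16)]
        pts += [(15, c) for c in range(29, -1, -1)]
        pts += [(r, 0) for r in range(14, 0, -1)]
        curve = FloatContour(np.array(pts, dtype=float), step=1.0)
        corrected = correct_contour(curve, ratio_threshold=1.0, march_step=1)
        assert corrected.n_corrected == 0
        assert enclosed_area(corrected) == pytest.approx(enclosed_area(curve))

    def test_area_monotone_and_idempotent_at_convergence(self):
        curve = notched_rectangle()
        once = correct_contour(curve, ratio_threshold=1.0, march_step=1)
        assert enclosed_area(once) >= enclosed_area(curve) - 1e-9
        twice = correct_contour(once, ratio_threshold=1.0, march_step=1)
        assert abs(twice.perimeter - once.perimeter) < 0.01


class TestRasterize:
    def test_circle_area_within_three_percent(self):
        angles = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([30 + 20 * np.sin(angles), 30 + 20 * np.cos(angles)])
        mask = rasterize(FloatContour(pts, step=0.3), (60, 60))
        assert mask.sum() == pytest.approx(np.pi * 400, rel=0.03)

    def test_orientation_independent(self):
        angles = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([20 + 10 * np.sin(angles), 20 + 12 * np.cos(angles)])
        cw = FloatContour(pts, step=0.5)
        ccw = FloatContour(pts[::-1].copy(), step=0.5)
        assert np.array_equal(rasterize(cw, (40, 40)), rasterize(ccw, (40, 40)))

    def test_axis_aligned_square_convention(self):
        pts = np.array([[2.0, 2.0], [2.0, 8.0], [8.0, 8.0], [8.0, 2.0]])
        mask = rasterize(FloatContour(pts, step=1.0), (12, 12))
        assert mask[3:8, 3:8].all()  # interior certainly filled
        assert not mask[0].any() and not mask[:, 0].any()


class TestOrientationHelpers:
    def test_signed_area_positive_for_display_clockwise(self):
        pts = np.array([[0.0, 0.0], [0.0, 4.0], [4.0, 4.0], [4.0, 0.0]])
        assert signed_area(pts) > 0

    def test_ensure_clockwise_flips_ccw_input(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]])
        fixed = ensure_clockwise(FloatContour(pts, step=1.0))
        assert signed_area(fixed.points) > 0
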