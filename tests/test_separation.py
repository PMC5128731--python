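"""Lung separation: DP maximum cost path, erosion split, constrained
reconstruction."""

from itertools import product

import numpy as np
import pytest
from scipy import ndimage as ndi

from lungtrace import phantom, preprocess, separation, tracing
from lungtrace.core import dice
from lungtrace.errors import EmptyBand, SeparationFailed, SplitFailed
from lungtrace.pipeline import _candidate_lungs
from lungtrace.separation import (
    constrained_reconstruct,
    erode_until_split,
    max_cost_path,
    separate_lungs,
)

_EIGHT = np.ones((3, 3), dtype=int)


def exhaustive_best_cost(weights: np.ndarray) -> float:
    rows, cols = weights.shape
    best = -np.inf
    for c0 in range(cols):
        for moves in product((-1, 0, 1), repeat=rows - 1):
            c, cost, ok = c0, weights[0, c0], True
            for r, move in enumerate(moves, start=1):
                c += move
                if not 0 <= c < cols:
                    ok = False
                    break
                cost += weights[r, c]
            if ok and cost > best:
                best = cost
    return best


class TestMaxCostPath:
    def test_uniform_weights_straight_leftmost_path(self):
        path = max_cost_path(np.ones((5, 4)))
        assert path == [(r, 0) for r in range(5)]

    def test_single_bright_column_is_followed(self):
        w = np.zeros((6, 5))
        w[:, 3] = 9.0
        assert max_cost_path(w) == [(r, 3) for r in range(6)]

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(2, 7))
        cols = int(rng.integers(1, 7))
        w = rng.random((rows, cols))
        path = max_cost_path(w)
        cost = sum(w[r, c] for r, c in path)
        assert cost == pytest.approx(exhaustive_best_cost(w), abs=1e-12)

    def test_band_restricts_columns(self):
        w = np.zeros((4, 6))
        w[:, 0] = 9.0  # best column outside the band
        path = max_cost_path(w, band=(2, 5))
        assert all(2 <= c < 5 for _, c in path)

    def test_empty_band_raises(self):
        with pytest.raises(EmptyBand):
            max_cost_path(np.ones((3, 3)), band=(2, 2))


def bridged_squares() -> np.ndarray:
    mask = np.zeros((20, 20), dtype=bool)
    mask[3:10, 2:9] = True
    mask[3:10, 11:18] = True
    mask[6, 9:11] = True  # 1-px bridge
    return mask


class TestErodeUntilSplit:
    def test_bridged_squares_split_after_one_erosion(self):
        s, n = erode_until_split(bridged_squares())
        assert n == 1
        _, comps = ndi.label(s, structure=_EIGHT)
        assert comps == 2

    def test_solid_disk_vanishes_without_splitting(self):
        rr, cc = np.indices((40, 40))
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 144
        with pytest.raises(SplitFailed):
            erode_until_split(disk)

    def test_already_split_mask_violates_precondition(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        with pytest.raises(ValueError):
            erode_until_split(mask)


class TestConstrainedReconstruct:
    def test_seed_equal_to_mask_is_fixed_point(self):
        mask = bridged_squares()
        assert np.array_equal(constrained_reconstruct(mask, mask), mask)

    def test_bridged_squares_rebuilt_minus_thin_cut(self):
        mask = bridged_squares()
        s, _ = erode_until_split(mask)
        rebuilt = constrained_reconstruct(s, mask)
        _, comps = ndi.label(rebuilt, structure=_EIGHT)
        assert comps == 2
        assert (mask & ~rebuilt).sum() <= 3  # only the cut is missing
        assert not (rebuilt & ~mask).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_contract_subset_components_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndi.gaussian_filter(rng.normal(size=(40, 40)), 4) > 0.0
        mask = ndi.binary_fill_holes(mask)
        labels, n = ndi.label(mask, structure=_EIGHT)
        if n == 0:
            pytest.skip("empty random mask")
        seed_mask = ndi.binary_erosion(mask, iterations=2, border_value=0)
        if not seed_mask.any():
            pytest.skip("seed vanished")
        rebuilt = constrained_reconstruct(seed_mask, mask)
        assert not (rebuilt & ~mask).any()
        _, n_seed = ndi.label(seed_mask, structure=_EIGHT)
        _, n_out = ndi.label(rebuilt, structure=_EIGHT)
        assert n_out == n_seed
        assert np.array_equal(constrained_reconstruct(rebuilt, mask), rebuilt)


class TestSeparateLungs:
    @staticmethod
    def lung_candidates(output):
        chest = preprocess.chest_mask(output.image)
        binary = tracing.binarize_within_chest(output.image, chest)
        return _candidate_lungs(binary, 50)

    def test_disjoint_lungs_need_no_separation(self, default_phantom):
        lung = self.lung_candidates(default_phantom)
        res = separate_lungs(lung, default_phantom.image)
        assert res.method == "none_needed"
        assert dice(res.left_mask, default_phantom.truth_left_mask) > 0.99
        assert dice(res.right_mask, default_phantom.truth_right_mask) > 0.99

    def test_fused_lungs_split_with_high_dice(self, fused_phantom):
        lung = self.lung_candidates(fused_phantom)
        res = separate_lungs(lung, fused_phantom.image)
        assert res.method in ("erosion", "path")
        assert not (res.left_mask & res.right_mask).any()
        assert dice(res.left_mask, fused_phantom.truth_left_mask) > 0.95
        assert dice(res.right_mask, fused_phantom.truth_right_mask) > 0.95

    def test_masks_are_disjoint_subsets_of_input(self, fused_phantom):
        lung = self.lung_candidates(fused_phantom)
        res = separate_lungs(lung, fused_phantom.image)
        assert not ((res.left_mask | res.right_mask) & ~lung).any()

    def test_empty_mask_fails(self):
        with pytest.raises(SeparationFailed):
            separate_lungs(np.zeros((16, 16), dtype=bool))

    def test_dp_fallback_cuts_an_unerodable_shape(self):
        # two fat lobes joined by a WIDE bright seam: erosion keeps failing
        # within the iteration budget, the intensity path cuts the seam
        mask = np.zeros((40, 60), dtype=bool)
        mask[5:35, 5:28] = True
        mask[5:35, 32:55] = True
        mask[5:35, 28:32] = True
        img = np.full(mask.shape, -800.0)
        img[:, 28:32] = 40.0  # junction tissue is bright
        res = separate_lungs(mask, img, max_iters=2)
        assert res.method in ("erosion", "path")
        assert not (res.left_mask & res.right_mask).any()
        labels = res.left_mask.astype(int) + 2 * res.right_mask.astype(int)
        assert (labels[:, :28] != 2).all() or (labels[:, 32:] != 1).all()
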