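"""En-face map assembly and morphological refinement."""

import numpy as np
import pytest
from skimage.morphology import dilation, disk

from ermmap.core import DataError, ERMMap
from ermmap.mapping import (
    PostprocessParams,
    build_map,
    optimize_postprocess,
    refine_map,
)
from ermmap.metrics import compute_metrics, confusion


class TestBuildMap:
    def test_stacking(self):
        vecs = [[0, 0, 0, 1], [0, 0, 1, 1], [0, 0, 0, 0]]
        m = build_map(vecs)
        assert m.grid.shape == (3, 4)
        assert m.grid.sum() == 3
        assert m.provenance == "raw"

    def test_rows_round_trip(self):
        vecs = [np.array([0, 1, 0]), np.array([1, 1, 0])]
        m = build_map(vecs)
        for i, v in enumerate(vecs):
            assert np.array_equal(m.grid[i], v)

    def test_all_zero(self):
        assert not build_map([np.zeros(5), np.zeros(5)]).grid.any()

    def test_ragged_rejected(self):
        with pytest.raises(DataError, match="ragged"):
            build_map([np.zeros(5), np.zeros(6)])


class TestRefineMap:
    def test_small_island_removed_large_region_kept(self):
        grid = np.zeros((20, 30), dtype=np.uint8)
        grid[2, 3:5] = 1  # 2-px island
        grid[8:13, 10:20] = 1  # 50-px region
        refined = refine_map(ERMMap(grid), PostprocessParams(10, 0))
        assert refined.grid[2, 3:5].sum() == 0
        assert refined.grid[8:13, 10:20].all()
        assert refined.provenance == "refined"

    def test_closing_fills_interior_hole(self):
        grid = np.ones((15, 15), dtype=np.uint8)
        grid[7, 7] = 0
        refined = refine_map(ERMMap(grid), PostprocessParams(0, 2))
        assert refined.grid[7, 7] == 1

    def test_zero_params_identity(self):
        rng = np.random.default_rng(5)
        grid = (rng.random((12, 18)) > 0.6).astype(np.uint8)
        refined = refine_map(ERMMap(grid), PostprocessParams(0, 0))
        assert np.array_equal(refined.grid, grid)

    @pytest.mark.parametrize("params", [
        PostprocessParams(10, 2),
        PostprocessParams(25, 3),
        PostprocessParams(0, 5),
    ])
    def test_idempotent(self, params):
        rng = np.random.default_rng(7)
        grid = (rng.random((40, 60)) > 0.7).astype(np.uint8)
        once = refine_map(ERMMap(grid), params)
        twice = refine_map(once, params)
        assert np.array_equal(once.grid, twice.grid)

    def test_positives_stay_inside_dilation_envelope(self):
        rng = np.random.default_rng(9)
        grid = (rng.random((30, 40)) > 0.75).astype(np.uint8)
        params = PostprocessParams(5, 3)
        refined = refine_map(ERMMap(grid), params)
        envelope = dilation(grid.astype(bool), disk(params.closing_radius))
        assert not np.any(refined.grid.astype(bool) & ~envelope)


class TestOptimizePostprocess:
    def _noisy_maps(self, seed=3):
        rng = np.random.default_rng(seed)
        truths, raws = [], []
        for _ in range(3):
            t = np.zeros((32, 64), dtype=np.uint8)
            t[8:24, 15:50] = 1
            noise_fp = rng.random(t.shape) > 0.97
            noise_fn = rng.random(t.shape) > 0.85
            r = t.copy()
            r[noise_fp] = 1
            r[t.astype(bool) & noise_fn] = 0
            truths.append(ERMMap(t, provenance="truth"))
            raws.append(ERMMap(r))
        return raws, truths

    def test_optimum_dominates_identity(self):
        raws, truths = self._noisy_maps()
        params, best_dice = optimize_postprocess(raws, truths)
        raw_dice = np.mean([
            compute_metrics(confusion(r, t)).dice
            for r, t in zip(raws, truths)
        ])
        assert best_dice >= raw_dice

    def test_single_candidate_returned_verbatim(self):
        raws, truths = self._noisy_maps()
        only = PostprocessParams(7, 1)
        params, _ = optimize_postprocess(raws, truths, grid=[only])
        assert params == only

    def test_identity_grid_on_perfect_maps_keeps_dice_one(self):
        t = np.zeros((10, 10), dtype=np.uint8)
        t[2:7, 3:8] = 1
        truth = ERMMap(t, provenance="truth")
        params, dice = optimize_postprocess(
            [ERMMap(t.copy())], [truth], grid=[PostprocessParams(0, 0)]
        )
        assert dice == 1.0
        assert (params.min_area, params.closing_radius) == (0, 0)

    def test_all_negative_truth_rejected(self):
        raw = ERMMap(np.zeros((5, 5), dtype=np.uint8))
        truth = ERMMap(np.zeros((5, 5), dtype=np.uint8), provenance="truth")
        with pytest.raises(DataError, match="specificity"):
            optimize_postprocess([raw], [truth])
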