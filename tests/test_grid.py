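"""Grid tiling, box categories, availability rules and MDC flags."""

import numpy as np
import pytest

from ccfdgrid import (AnalysisConfig, BinaryCCFDMap, EnFaceImage, MaskImage,
                      box_ccfd, classify_boxes, low_signal_mask,
                      make_target_box, mdc_change, tile_grid)
from ccfdgrid.core import DEFICIT, FLOW, INVALID


def annotation(shape, pixels):
    arr = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        arr[r, c] = True
    return MaskImage(arr, kind="hypertd")


class TestMakeTargetBox:
    def test_centroid_box_is_centered(self):
        ann = annotation((500, 500), [(250, 250)])
        assert make_target_box(ann) == (213, 213)  # 250 - 74 // 2

    def test_clamped_at_the_border(self):
        ann = annotation((500, 500), [(10, 10)])
        assert make_target_box(ann) == (0, 0)

    def test_empty_annotation_is_an_error(self):
        with pytest.raises(ValueError):
            make_target_box(annotation((100, 100), []))


class TestTileGrid:
    @pytest.mark.parametrize("anchor,expected", [((0, 0), 36), ((52, 52), 36)])
    def test_500px_raster_tiles_6x6(self, anchor, expected):
        grid = tile_grid((500, 500), anchor)
        assert len(grid.boxes) == expected

    def test_single_box_raster(self):
        grid = tile_grid((74, 74), (0, 0))
        assert len(grid.boxes) == 1 and grid.target_box_id == 0

    def test_boxes_are_disjoint_and_aligned(self):
        grid = tile_grid((500, 500), (213, 213))
        cover = np.zeros((500, 500), dtype=int)
        for box_id, _, _ in grid.boxes:
            sl = grid.box_slices(box_id)
            cover[sl] += 1
        assert cover.max() == 1
        assert (cover[grid.box_slices(grid.target_box_id)] == 1).all()


class TestClassifyBoxes:
    def _case(self, n, lesion_center):
        side = 74 * n
        ann = annotation((side, side), [lesion_center])
        grid = tile_grid((side, side), make_target_box(ann))
        cats = classify_boxes(grid, [ann] * 4, ann)
        return grid, cats

    def test_center_lesion_3x3_grid(self):
        _, cats = self._case(3, (111, 111))
        vals = list(cats.values())
        assert vals.count("target") == 1
        assert vals.count("adjacent_background") == 8
        assert vals.count("nonadjacent_background") == 0

    def test_center_lesion_5x5_grid(self):
        _, cats = self._case(5, (185, 185))
        vals = list(cats.values())
        assert (vals.count("target"), vals.count("adjacent_background"),
                vals.count("nonadjacent_background")) == (1, 8, 16)

    def test_category_counts_partition_all_boxes(self):
        grid, cats = self._case(5, (185, 185))
        assert len(cats) == len(grid.boxes)

    def test_target_spillover_becomes_nontarget_hypertd(self):
        side = 74 * 3
        ann = annotation((side, side), [(111, 111)])
        big = np.zeros((side, side), dtype=bool)
        big[100:160, 100:160] = True  # lesion spills into neighbour boxes
        grid = tile_grid((side, side), make_target_box(ann))
        cats = classify_boxes(grid, [MaskImage(big, kind="hypertd")] * 4, ann)
        assert list(cats.values()).count("target") == 1
        assert list(cats.values()).count("nontarget_hypertd") >= 1


class TestLowSignalMask:
    def test_floor_population_is_masked_body_is_not(self):
        # floor 10 on 5% of pixels, body 1000: cutoff 10*10^0.5 = 31.6
        arr = np.full((100, 100), 1000.0)
        arr[:5, :] = 10.0
        mask = low_signal_mask(EnFaceImage(arr))
        assert mask.pixels[:5].all() and not mask.pixels[5:].any()

    def test_dim_body_within_5db_of_floor_is_masked_too(self):
        arr = np.full((100, 100), 25.0)
        arr[:5, :] = 10.0
        mask = low_signal_mask(EnFaceImage(arr))
        assert mask.pixels.all()  # 25 < 31.6

    def test_constant_raster_masks_everything(self):
        mask = low_signal_mask(EnFaceImage(np.full((20, 20), 7.0)))
        assert mask.pixels.all()  # c < c * 10^0.5, forced by the formula


class TestBoxCCFD:
    def _map(self, state):
        return BinaryCCFDMap(np.asarray(state, dtype=np.uint8))

    def test_half_deficit_fully_valid(self):
        state = np.full((74, 74), FLOW)
        state[:37] = DEFICIT
        pct, vfrac, inc = box_ccfd(self._map(state), (slice(0, 74), slice(0, 74)))
        assert (pct, vfrac, inc) == (50.0, 1.0, True)

    @pytest.mark.parametrize("frac,included", [(0.30, False), (0.25, True)])
    def test_availability_rule_is_strictly_more_than_25(self, frac, included):
        state = np.full((74, 74), FLOW)
        n_bad = int(round(frac * 74 * 74))
        state.ravel()[:n_bad] = INVALID
        _, _, inc = box_ccfd(self._map(state), (slice(0, 74), slice(0, 74)))
        assert inc == included

    def test_no_available_pixels_reports_missing(self):
        state = np.full((74, 74), INVALID)
        pct, vfrac, _ = box_ccfd(self._map(state), (slice(0, 74), slice(0, 74)))
        assert pct is None and vfrac == 0.0

    def test_low_signal_pixels_leave_denominator(self):
        state = np.full((74, 74), FLOW)
        state[:37] = DEFICIT
        low = np.zeros((74, 74), dtype=bool)
        low[:37] = True  # every deficit pixel is also low-signal
        pct, _, _ = box_ccfd(self._map(state), (slice(0, 74), slice(0, 74)),
                             MaskImage(low, kind="low_signal"))
        assert pct == 0.0


class TestMDCChange:
    def test_showcase_series_flags_post_onset_rise(self):
        # 8.8 -> 7.3 (no change) -> 25.6, 28.3 (marked change)
        flags = mdc_change([8.8, 7.3, 25.6, 28.3])
        assert flags == [None, False, True, True]

    def test_change_of_exactly_5_is_not_marked(self):
        assert mdc_change([10.0, 15.0])[1] is False

    def test_decrease_beyond_mdc_is_marked(self):
        assert mdc_change([10.0, 4.0])[1] is True

    def test_missing_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            mdc_change([None, 10.0, 12.0, 13.0])
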