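import numpy as np
import pytest

from echocount import (
    DetectParams,
    EchogramSpec,
    InputError,
    assign_depth,
    assign_position,
    binarize,
    detect_fish,
    label_and_measure,
    mask_water_column,
    preprocess,
    score_detections,
    synthesize_echogram,
)
from echocount.echogen import Echogram


class TestPreprocess:
    def test_constant_image_removed(self):
        out = preprocess(np.full((100, 80), 37.0))
        assert np.all(out == 0.0)

    def test_small_bright_blob_survives_background_removal(self):
        img = np.zeros((120, 120))
        img[50:55, 60:65] = 200.0
        out = preprocess(img)
        assert out[52, 62] >= 199.0  # far smaller than the 40x40 element

    def test_single_pixel_impulse_removed_by_median(self):
        img = np.zeros((60, 60))
        img[30, 30] = 255.0
        assert preprocess(img).max() == 0.0

    def test_too_small_image_rejected(self):
        with pytest.raises(InputError):
            preprocess(np.zeros((2, 2)))


class TestBinarize:
    def test_all_zero_yields_empty_mask(self):
        assert not binarize(np.zeros((4, 4))).any()

    def test_hand_arithmetic(self):
        img = np.array([[0.0, 0.0], [0.0, 100.0]])  # mean 25, threshold 5
        assert binarize(img).sum() == 1

    def test_uniform_positive_image_fully_set(self):
        assert binarize(np.full((3, 3), 7.0)).all()

    def test_external_reference_mean(self):
        img = np.array([[1.0, 10.0]])
        ref = np.full((2, 2), 100.0)  # threshold 20
        assert binarize(img, reference=ref).sum() == 0


class TestWaterColumnMask:
    def test_index_arithmetic(self):
        mask = np.ones((120, 6), bool)
        out = mask_water_column(mask, surface_row=10,
                                bottom_profile=np.full(6, 100), margin_px=2)
        rows = np.flatnonzero(out[:, 0])
        assert rows.min() == 13 and rows.max() == 97

    def test_empty_mask_stays_empty(self):
        out = mask_water_column(np.zeros((50, 4), bool), 5, np.full(4, 40), 2)
        assert not out.any()

    def test_overwide_margin_clears_everything(self):
        out = mask_water_column(np.ones((50, 4), bool), 5, np.full(4, 40), 30)
        assert not out.any()

    def test_inverted_geometry_rejected(self):
        with pytest.raises(InputError):
            mask_water_column(np.ones((50, 4), bool), 45, np.full(4, 40), 2)

    def test_profile_length_checked(self):
        with pytest.raises(InputError):
            mask_water_column(np.ones((50, 4), bool), 5, np.full(7, 40), 2)


class TestLabelAndMeasure:
    def test_empty_mask(self):
        assert label_and_measure(np.zeros((10, 10), bool)) == []

    def test_two_separated_blobs(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True   # area 9
        mask[6:10, 6:8] = True  # area 8
        out = label_and_measure(mask, min_area_px=4)
        assert [(lab, area) for lab, area, _ in out] == [(1, 9), (2, 8)]
        assert out[0][2] == (2.0, 2.0)

    def test_diagonal_adjacency_merges_blobs(self):
        # two blobs touching only diagonally: 8-connectivity counts one fish,
        # reproducing the known merging failure for closely adjacent fish
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[4:7, 4:7] = True
        out = label_and_measure(mask, min_area_px=4)
        assert len(out) == 1 and out[0][1] == 18

    def test_min_area_filter_and_renumbering(self):
        mask = np.zeros((8, 20), bool)
        mask[1, 1] = True          # area 1: dropped
        mask[3:5, 5:8] = True      # area 6: kept, becomes id 1
        mask[6:8, 12:15] = True    # area 6: kept, becomes id 2
        out = label_and_measure(mask, min_area_px=4)
        assert [lab for lab, _, _ in out] == [1, 2]


class TestDepthAndPosition:
    def test_depth_scale_197_pixels_per_meter(self):
        assert assign_depth(197, 1970, 10.0) == pytest.approx(1.0)
        assert assign_depth(985, 1970, 10.0) == pytest.approx(5.0)
        assert assign_depth(0, 1970, 10.0) == 0.0

    def test_depth_is_linear(self):
        a, b = 123, 456
        assert assign_depth(a + b, 1970, 10.0) == pytest.approx(
            assign_depth(a, 1970, 10.0) + assign_depth(b, 1970, 10.0))

    def test_row_bounds_checked(self):
        with pytest.raises(InputError):
            assign_depth(2000, 1970, 10.0)

    def test_interpolation_between_fixes(self):
        fixes = [(0, 50.000, 19.000), (10, 50.010, 19.010)]
        lat, lon, ok = assign_position(5.0, fixes)
        assert ok and lat == pytest.approx(50.005) and lon == pytest.approx(19.005)

    def test_exact_fix_and_extrapolation_clamp(self):
        fixes = [(2, 50.0, 19.0), (12, 50.4, 19.4)]
        assert assign_position(2, fixes)[:2] == (50.0, 19.0)
        assert assign_position(0, fixes)[:2] == (50.0, 19.0)
        assert assign_position(99, fixes)[:2] == pytest.approx((50.4, 19.4))

    def test_no_fixes(self):
        assert assign_position(5.0, []) == (None, None, False)


class TestPipeline:
    def test_blank_scene_gives_empty_table(self):
        echo, _ = synthesize_echogram(EchogramSpec(n_fish=0, seed=2))
        assert len(detect_fish(echo)) == 0

    def test_five_fish_recovered_with_positions(self, default_scene):
        spec, echo, truth = default_scene
        table = detect_fish(echo)
        assert len(table) == len(truth)
        recall, precision = score_detections(truth, table.detections, 10.0)
        assert recall == 1.0 and precision == 1.0
        for d in table:
            assert d.gps_valid and d.lat is not None
            assert 0.0 <= d.depth_m <= echo.range_m

    def test_ids_consecutive_from_one(self, default_scene):
        table = detect_fish(default_scene[1])
        assert [d.id for d in table] == list(range(1, len(table) + 1))

    def test_removing_fixes_only_invalidates_gps(self, default_scene):
        _, echo, _ = default_scene
        stripped = Echogram(intensity=echo.intensity, range_m=echo.range_m,
                            surface_row=echo.surface_row,
                            bottom_profile=echo.bottom_profile, gps_fixes=[])
        t1, t2 = detect_fish(echo), detect_fish(stripped)
        assert len(t1) == len(t2)
        assert all(not d.gps_valid and d.lat is None for d in t2)
        assert [d.area_px for d in t1] == [d.area_px for d in t2]

    def test_invariant_to_moderate_constant_offset(self, default_scene):
        _, echo, _ = default_scene
        shifted = Echogram(
            intensity=np.clip(echo.intensity.astype(int) + 15, 0, 255).astype(np.uint8),
            range_m=echo.range_m, surface_row=echo.surface_row,
            bottom_profile=echo.bottom_profile, gps_fixes=echo.gps_fixes)
        t1, t2 = detect_fish(echo), detect_fish(shifted)
        assert len(t1) == len(t2)
        assert [d.id for d in t1] == [d.id for d in t2]

    def test_count_monotone_in_min_area_and_threshold(self, default_scene):
        _, echo, _ = default_scene
        counts_area = [len(detect_fish(echo, DetectParams(min_area_px=a)))
                       for a in (1, 4, 30, 80, 200)]
        assert counts_area == sorted(counts_area, reverse=True)
        counts_thr = [len(detect_fish(echo, DetectParams(threshold_factor=f)))
                      for f in (0.05, 0.2, 0.5, 0.9, 3.0)]
        assert counts_thr == sorted(counts_thr, reverse=True)
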