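import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from coloc import (
    RasterImage,
    ROILabels,
    SelectionParams,
    clean_specks,
    dilate,
    erode,
    fill_gaps,
    label_components,
    load_labels,
    save_labels,
    select_rois,
    threshold_mask,
)
from oracles import (
    clean_loop,
    dilate_loop,
    erode_loop,
    fill_loop,
    flood_fill_label,
    percentile_interp,
)

masks_6x6 = hnp.arrays(bool, (6, 6), elements=st.booleans())


class TestThreshold:
    def test_constant_plane_yields_empty_mask(self):
        plane = np.full((7, 7), 0.3)
        for t in (0, 50, 90, 100):
            assert not threshold_mask(plane, t).any()

    def test_ten_distinct_values_at_90_keeps_only_maximum(self, rng):
        vals = rng.permutation(np.linspace(0.05, 0.95, 10)).reshape(2, 5)
        mask = threshold_mask(vals, 90)
        expected = vals > percentile_interp(vals, 90)
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 1
        assert vals[mask][0] == vals.max()

    def test_threshold_zero_excludes_minimum_only(self, rng):
        vals = rng.permutation(np.arange(12) / 12.0).reshape(3, 4)
        mask = threshold_mask(vals, 0)
        assert mask.sum() == 11
        assert not mask[vals == vals.min()].any()

    def test_matches_sorted_interpolation_oracle(self, rng):
        plane = rng.random((9, 9))
        for t in (10.0, 37.5, 90.0):
            np.testing.assert_array_equal(
                threshold_mask(plane, t), plane > percentile_interp(plane, t)
            )

    @pytest.mark.parametrize("bad", [-1, 101])
    def test_out_of_range_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2)), bad)


class TestMorphologyExamples:
    def test_erode_empty_stays_empty(self):
        empty = np.zeros((5, 5), bool)
        for s in (0, 2, 3, 5):
            assert not erode(empty, s).any()

    def test_erode_all_true_3x3_by_3_leaves_center(self):
        out = erode(np.ones((3, 3), bool), 3)
        expected = np.zeros((3, 3), bool)
        expected[1, 1] = True
        np.testing.assert_array_equal(out, expected)

    def test_dilate_center_pixel_by_3_gives_3x3_block(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        np.testing.assert_array_equal(dilate(mask, 3), dilate_loop(mask, 3))
        assert dilate(mask, 3).sum() == 9

    def test_fill_closes_one_pixel_hole_in_ring(self):
        mask = np.ones((5, 5), bool)
        mask[2, 2] = False  # pinhole
        out = fill_gaps(mask, 3)
        assert out[2, 2]
        np.testing.assert_array_equal(out, fill_loop(mask, 3))

    def test_clean_removes_speck_keeps_block(self):
        mask = np.zeros((9, 9), bool)
        mask[1, 1] = True  # isolated speck
        mask[3:8, 3:8] = True  # 5x5 block
        out = clean_specks(mask, 3)
        assert not out[1, 1]
        assert out[4:7, 4:7].all()
        np.testing.assert_array_equal(out, clean_loop(mask, 3))

    @pytest.mark.parametrize("op", [erode, dilate, fill_gaps, clean_specks])
    @pytest.mark.parametrize("size", [0, 1])
    def test_size_zero_and_one_are_identity(self, rng, op, size):
        mask = rng.random((6, 6)) > 0.5
        np.testing.assert_array_equal(op(mask, size), mask)

    @pytest.mark.parametrize("op", [erode, dilate, fill_gaps, clean_specks])
    def test_negative_size_rejected(self, op):
        with pytest.raises(ValueError):
            op(np.ones((3, 3), bool), -1)


class TestMorphologyProperties:
    @given(mask=masks_6x6, size=st.sampled_from([0, 2, 3]))
    def test_all_ops_match_loop_oracle(self, mask, size):
        np.testing.assert_array_equal(erode(mask, size), erode_loop(mask, size))
        np.testing.assert_array_equal(dilate(mask, size), dilate_loop(mask, size))
        np.testing.assert_array_equal(fill_gaps(mask, size), fill_loop(mask, size))
        np.testing.assert_array_equal(clean_specks(mask, size), clean_loop(mask, size))

    @given(mask=masks_6x6, size=st.sampled_from([2, 3, 4]))
    def test_opening_anti_extensive_closing_extensive(self, mask, size):
        # out-of-image pixels count as background, so closing can clip
        # foreground touching the border; extensivity is asserted on the
        # padded domain where no foreground touches the border
        opened = clean_specks(mask, size)
        assert not (opened & ~mask).any()  # opening subset of mask, always
        padded = np.pad(mask, size, constant_values=False)
        closed = fill_gaps(padded, size)
        assert not (padded & ~closed).any()  # mask subset of closing

    @given(mask=masks_6x6, size=st.sampled_from([2, 3, 4]))
    def test_opening_and_closing_idempotent(self, mask, size):
        opened = clean_specks(mask, size)
        closed = fill_gaps(mask, size)
        np.testing.assert_array_equal(clean_specks(opened, size), opened)
        np.testing.assert_array_equal(fill_gaps(closed, size), closed)

    @given(mask=masks_6x6, size=st.sampled_from([3, 5]))
    def test_erode_dilate_dual_under_complement_on_padded_domain(self, mask, size):
        # the identity holds away from the border; pad so the border plays
        # no role, then compare on the original window
        pad = size
        padded = np.pad(mask, pad, constant_values=False)
        dual = ~dilate(~padded, size)
        direct = erode(padded, size)
        np.testing.assert_array_equal(
            dual[pad:-pad, pad:-pad], direct[pad:-pad, pad:-pad]
        )


class TestLabelComponents:
    def test_empty_mask(self):
        out = label_components(np.zeros((4, 4), bool))
        assert out.n_selected == 0
        assert not out.labels.any()

    def test_two_blocks_ranked_by_size(self):
        mask = np.zeros((6, 8), bool)
        mask[4:5, 0:2] = True  # size 2, earlier in scan order
        mask[1:3, 4:7] = True  # size 6
        out = label_components(mask)
        assert out.n_selected == 2
        assert (out.labels[1:3, 4:7] == 1).all()
        assert (out.labels[4:5, 0:2] == 2).all()
        assert list(out.region_sizes()) == [6, 2]

    def test_diagonal_pixels_are_separate_components(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[1, 1] = True
        out = label_components(mask)
        assert out.n_selected == 2

    def test_equal_sizes_tie_broken_by_first_pixel(self):
        mask = np.zeros((4, 6), bool)
        mask[2, 4:6] = True
        mask[0, 0:2] = True
        out = label_components(mask)
        assert (out.labels[0, 0:2] == 1).all()
        assert (out.labels[2, 4:6] == 2).all()

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(60):
            mask = rng.random((20, 20)) < rng.uniform(0.2, 0.7)
            out = label_components(mask)
            comps = flood_fill_label(mask)
            assert out.n_selected == len(comps)
            for lab, comp in enumerate(comps, start=1):
                got = set(zip(*np.nonzero(out.labels == lab)))
                assert got == comp
            sizes = out.region_sizes()
            assert all(sizes[i] >= sizes[i + 1] for i in range(len(sizes) - 1))


class TestSelectRois:
    def test_three_blob_fixture_n2_keeps_two_largest(self, three_blob_pair):
        img, gt = three_blob_pair
        labels = select_rois(img, SelectionParams(threshold=90, shrink=0, clean=3, n=2))
        assert labels.n_selected == 2
        for k in (1, 2):
            truth = gt.labels == k
            got = labels.labels == k
            jaccard = (truth & got).sum() / (truth | got).sum()
            assert jaccard > 0.9

    def test_n_saturates_at_component_count(self, three_blob_pair):
        img, _ = three_blob_pair
        labels = select_rois(img, SelectionParams(threshold=90, shrink=0, clean=3, n=50))
        assert labels.n_selected >= 3  # everything available is returned
        sizes = labels.region_sizes()
        assert all(sizes[i] >= sizes[i + 1] for i in range(len(sizes) - 1))

    def test_all_black_image_warns_and_returns_zero_labels(self, caplog):
        img = RasterImage(np.zeros((16, 16, 2)))
        with caplog.at_level("WARNING", logger="coloc"):
            labels = select_rois(img, SelectionParams(threshold=90, n=3))
        assert labels.n_selected == 0
        assert labels.labels.shape == (16, 16)
        assert any("empty mask" in rec.message for rec in caplog.records)

    def test_selection_subset_of_thresholded_morphology(self, three_blob_pair):
        from coloc import to_grayscale

        img, _ = three_blob_pair
        params = SelectionParams(threshold=90, shrink=0, clean=3, n=2)
        labels = select_rois(img, params)
        mask = clean_specks(threshold_mask(to_grayscale(img), 90), 3)
        assert not ((labels.labels > 0) & ~mask).any()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SelectionParams(threshold=150)
        with pytest.raises(ValueError):
            SelectionParams(shrink=-1)
        with pytest.raises(ValueError):
            SelectionParams(n=0)


class TestLabelInterchange:
    @pytest.mark.parametrize("suffix", ["png", "tif"])
    def test_round_trip(self, tmp_path, three_blob_pair, suffix):
        _, gt = three_blob_pair
        path = tmp_path / f"labels.{suffix}"
        save_labels(gt, path)
        back = load_labels(path)
        np.testing.assert_array_equal(back.labels, gt.labels)
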