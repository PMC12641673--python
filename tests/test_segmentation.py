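"""Thresholding, connectivity labeling and object filtering semantics."""

import numpy as np
import pytest

from phagometry.config import SegmentationParams
from phagometry.masking import mask_channel
from phagometry.segmentation import (
    EmptyMaskError,
    filter_outliers,
    filter_small,
    label_components,
    segment_cells,
    threshold_channel,
)
from phagometry.volumes import IntensityVolume, LabelVolume, StackGeometry

from .oracles import flood_fill_components


def _masked(values, geometry, mask=None):
    vol = IntensityVolume(values=values, geometry=geometry)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return mask_channel(vol, mask)


def _label_volume(arr, geometry):
    return LabelVolume.from_array(arr.astype(np.int32), geometry, name_prefix="cell")


class TestThreshold:
    def test_otsu_separates_two_level_phantom(self, iso2_geometry, rng):
        vals = np.full(iso2_geometry.shape, 10, dtype=np.uint16)
        cells = rng.random(iso2_geometry.shape) < 0.1
        vals[cells] = 200
        binary, thresh = threshold_channel(_masked(vals, iso2_geometry), SegmentationParams())
        np.testing.assert_array_equal(binary, cells)
        assert 10 <= thresh < 200

    def test_fixed_threshold_above_max_yields_empty(self, iso2_geometry):
        vals = np.full(iso2_geometry.shape, 200, dtype=np.uint8)
        params = SegmentationParams(threshold_method="fixed", fixed_threshold=255)
        binary, _ = threshold_channel(_masked(vals, iso2_geometry), params)
        assert not binary.any()

    def test_otsu_on_all_ones_mask_equals_unmasked(self, iso2_geometry, rng):
        vals = rng.integers(0, 255, iso2_geometry.shape).astype(np.uint16)
        from skimage.filters import threshold_otsu

        _, thresh = threshold_channel(_masked(vals, iso2_geometry), SegmentationParams())
        assert thresh == pytest.approx(float(threshold_otsu(vals.ravel())))

    def test_empty_mask_raises(self, iso2_geometry):
        vals = np.zeros(iso2_geometry.shape, dtype=np.uint16)
        with pytest.raises(EmptyMaskError, match="empty mask"):
            threshold_channel(_masked(vals, iso2_geometry), SegmentationParams())


class TestLabelComponents:
    def test_corner_touching_pair_connectivity(self, iso2_geometry):
        binary = np.zeros(iso2_geometry.shape, dtype=bool)
        binary[4, 4, 4] = True
        binary[5, 5, 5] = True  # shares only a corner
        assert len(label_components(binary, 26, iso2_geometry).present_labels()) == 1
        assert len(label_components(binary, 6, iso2_geometry).present_labels()) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_sparse_volumes_match_flood_fill_oracle(self, connectivity, rng):
        g = StackGeometry(voxel_size_um=(1.0, 1.0, 1.0), shape=(64, 64, 64))
        for _ in range(10):
            binary = rng.random(g.shape) < 0.02
            lv = label_components(binary, connectivity, g)
            oracle = flood_fill_components(binary, connectivity)
            assert len(lv.present_labels()) == len(oracle)
            # memberships: every oracle component maps to exactly one label
            for comp in oracle:
                labels = {int(lv.labels[v]) for v in comp}
                assert len(labels) == 1
                label = labels.pop()
                assert int((lv.labels == label).sum()) == len(comp)

    def test_labels_follow_raster_scan_order(self, iso2_geometry):
        binary = np.zeros(iso2_geometry.shape, dtype=bool)
        binary[10, 10, 10] = True
        binary[2, 2, 2] = True
        lv = label_components(binary, 26, iso2_geometry)
        assert lv.labels[2, 2, 2] == 1
        assert lv.labels[10, 10, 10] == 2

    def test_invariant_under_translation(self, rng):
        g = StackGeometry(voxel_size_um=(1.0, 1.0, 1.0), shape=(32, 32, 32))
        binary = np.zeros(g.shape, dtype=bool)
        binary[4:12, 4:12, 4:12] = rng.random((8, 8, 8)) < 0.3
        a = label_components(binary, 26, g)
        b = label_components(np.roll(binary, (5, 5, 5), axis=(0, 1, 2)), 26, g)
        assert len(a.present_labels()) == len(b.present_labels())


class TestFilters:
    def test_strict_less_than_100_semantics(self, iso2_geometry):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        arr.flat[:99] = 1  # 99-voxel object -> removed
        arr[16].flat[:100] = 2  # 100-voxel object -> kept
        out, removed = filter_small(_label_volume(arr, iso2_geometry), 100)
        assert removed == 1
        assert out.present_labels() == [1]
        assert int((out.labels == 1).sum()) == 100

    def test_counts_after_filtering(self, iso2_geometry, rng):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        sizes = [5, 20, 99, 100, 150, 3, 101, 250, 40, 500]
        start = 0
        for label, size in enumerate(sizes, start=1):
            arr.flat[start : start + size] = label
            start += size + 7
        out, removed = filter_small(_label_volume(arr, iso2_geometry), 100)
        assert removed == 5  # sizes 5, 20, 99, 3, 40 fall below 100
        assert len(out.present_labels()) == 5
        # surviving voxel sets untouched
        assert np.count_nonzero(out.labels) == 100 + 150 + 101 + 250 + 500

    def test_empty_volume_passthrough(self, iso2_geometry):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        out, removed = filter_small(_label_volume(arr, iso2_geometry), 100)
        assert removed == 0
        assert out.present_labels() == []

    def test_upper_mad_rule_on_printed_volume_set(self):
        """Volumes {1000,1100,1200,1300,1400,50000}: cutoff ~1917, so only
        the 50000-voxel artifact is removed."""
        g = StackGeometry(voxel_size_um=(1.0, 1.0, 1.0), shape=(60, 40, 40))
        arr = np.zeros(g.shape, dtype=np.int32)
        sizes = [1000, 1100, 1200, 1300, 1400, 50000]
        start = 0
        for label, size in enumerate(sizes, start=1):
            arr.flat[start : start + size] = label
            start += size + 1
        out, removed = filter_outliers(_label_volume(arr, g), "upper_mad", 3.0)
        assert removed == 1
        counts = np.bincount(out.labels.ravel())[1:]
        assert sorted(counts.tolist()) == [1000, 1100, 1200, 1300, 1400]

    def test_mad_zero_removes_nothing(self, iso2_geometry, caplog):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        for label in (1, 2, 3):
            arr[label * 4].flat[:50] = label
        with caplog.at_level("WARNING"):
            out, removed = filter_outliers(_label_volume(arr, iso2_geometry), "upper_mad", 3.0)
        assert removed == 0
        assert "MAD is 0" in caplog.text

    def test_rule_none_is_identity(self, iso2_geometry):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        arr[0, 0, :5] = 1
        lv = _label_volume(arr, iso2_geometry)
        out, removed = filter_outliers(lv, "none")
        assert removed == 0
        np.testing.assert_array_equal(out.labels, lv.labels)

    def test_fewer_than_three_objects_skips(self, iso2_geometry, caplog):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        arr[0, 0, :5] = 1
        arr[1, 0, :500] = 2
        with caplog.at_level("WARNING"):
            _, removed = filter_outliers(_label_volume(arr, iso2_geometry), "upper_mad", 3.0)
        assert removed == 0


class TestSegmentCells:
    def test_total_foreground_equals_sum_of_survivors(self, iso2_geometry, rng):
        vals = np.full(iso2_geometry.shape, 10, dtype=np.uint16)
        blob = rng.random(iso2_geometry.shape) < 0.08
        vals[blob] = 200
        result = segment_cells(_masked(vals, iso2_geometry), SegmentationParams(min_object_voxels=5, outlier_rule="none"))
        counts = np.bincount(result.cell_labels.labels.ravel())[1:]
        assert counts.sum() == np.count_nonzero(result.cell_labels.labels)
        assert (counts >= 5).all()
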