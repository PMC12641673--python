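"""Solidity, equivalent radius, region assignment, occupancy, summaries."""

import math

import numpy as np
import pytest

from phagometry.morphometry import (
    UNASSIGNED,
    assign_region,
    cell_volume,
    classify_morphology,
    equiv_radius,
    hull_solidity,
    measure_cells,
    occupancy,
    summarize,
)
from phagometry.volumes import LabelVolume, StackGeometry

from .oracles import hull_voxel_count


def _cube(side):
    r = np.arange(side)
    return np.array(np.meshgrid(r, r, r, indexing="ij")).reshape(3, -1).T


def _cross_19():
    """3D orthogonal cross: three 7-voxel arms through one center."""
    vox = {(0, 0, 0)}
    for d in range(1, 4):
        vox |= {(d, 0, 0), (-d, 0, 0), (0, d, 0), (0, -d, 0), (0, 0, d), (0, 0, -d)}
    return np.array(sorted(vox))


class TestCellVolume:
    def test_scaling_rule(self):
        g = StackGeometry(voxel_size_um=(2.0, 2.0, 2.0), shape=(4, 4, 4))
        assert cell_volume(1000, g) == 8000.0

    def test_empty_object_rejected(self):
        g = StackGeometry(voxel_size_um=(1.0, 1.0, 1.0), shape=(4, 4, 4))
        with pytest.raises(ValueError):
            cell_volume(0, g)


class TestHullSolidity:
    def test_filled_cube_is_convex(self):
        hull_voxels, solidity = hull_solidity(_cube(5))
        assert (hull_voxels, solidity) == (125, 1.0)

    def test_digital_ball_is_convex(self):
        r = 4
        pts = np.array(
            [
                (i, j, k)
                for i in range(-r, r + 1)
                for j in range(-r, r + 1)
                for k in range(-r, r + 1)
                if i * i + j * j + k * k <= r * r
            ]
        )
        _, solidity = hull_solidity(pts)
        assert solidity == 1.0

    def test_orthogonal_cross_19_over_63(self):
        """The cross's hull is the L1 ball of radius 3 (octahedron): the
        centered octahedral number 63 -> solidity 19/63."""
        vox = _cross_19()
        assert len(vox) == 19
        octahedron = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if abs(i) + abs(j) + abs(k) <= 3
        )
        assert octahedron == 63
        hull_voxels, solidity = hull_solidity(vox)
        assert hull_voxels == 63
        assert solidity == pytest.approx(19 / 63)
        assert hull_voxel_count(vox) == 63

    def test_single_voxel_and_line_degenerate_to_one(self):
        assert hull_solidity(np.array([[3, 3, 3]])) == (1, 1.0)
        line = np.array([[0, 0, k] for k in range(7)])
        assert hull_solidity(line) == (7, 1.0)

    def test_random_small_objects_match_delaunay_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 16))
            pts = np.unique(rng.integers(0, 8, size=(n, 3)), axis=0)
            hull_voxels, solidity = hull_solidity(pts)
            assert hull_voxels == hull_voxel_count(pts)
            assert hull_voxels >= len(pts)
            assert 0 < solidity <= 1

    def test_continuous_mode_cube_exact(self):
        g = StackGeometry(voxel_size_um=(2.0, 2.0, 2.0), shape=(8, 8, 8))
        hull_um3, solidity = hull_solidity(_cube(5), g, hull_mode="continuous")
        assert hull_um3 == pytest.approx(125 * 8.0)
        assert solidity == pytest.approx(1.0)


class TestEquivRadius:
    def test_sphere_identity_and_homogeneity(self):
        v10 = 4.0 / 3.0 * math.pi * 1000.0
        assert equiv_radius(v10) == pytest.approx(10.0)
        assert equiv_radius(8 * v10) == pytest.approx(20.0)

    def test_mean_volume_consistency_with_observed_radii(self):
        # a 5393 µm³ cell has equivalent radius ~10.88 µm, in the 9-12 µm
        # range typical of periductal macrophages
        assert equiv_radius(5393.0) == pytest.approx(10.88, abs=0.005)


class TestClassify:
    @pytest.mark.parametrize(
        "solidity,expected",
        [(0.12, "ramified"), (0.70, "ameboid"), (0.5, "ameboid"), (0.499999, "ramified")],
    )
    def test_threshold_rule(self, solidity, expected):
        assert classify_morphology(solidity, 0.5) == expected


class TestAssignRegion:
    def _rois(self, geometry):
        arr = np.zeros(geometry.shape, dtype=np.int16)
        arr[:, :, 4] = 1  # "ed" plane
        arr[:, :, 12] = 2  # "vva" plane
        return LabelVolume(labels=arr, geometry=geometry, label_names={1: "ed", 2: "vva"})

    def test_overlapping_cell_distance_zero(self, iso2_geometry):
        rois = self._rois(iso2_geometry)
        assert assign_region(np.array([[5, 5, 4]]), rois, 10.0) == "ed"

    def test_beyond_max_distance_unassigned(self, iso2_geometry):
        rois = self._rois(iso2_geometry)
        assert assign_region(np.array([[5, 5, 20]]), rois, 5.0) == UNASSIGNED

    def test_equidistant_tie_breaks_lexicographically(self, iso2_geometry):
        rois = self._rois(iso2_geometry)
        cell = np.array([[5, 5, 8]])  # 4 voxels from both planes
        # brute-force check of equidistance
        d_ed = abs(8 - 4) * 2.0
        d_vva = abs(8 - 12) * 2.0
        assert d_ed == d_vva
        assert assign_region(cell, rois, 20.0) == "ed"

    def test_empty_roi_map_warns_unassigned(self, iso2_geometry, caplog):
        rois = LabelVolume(
            labels=np.zeros(iso2_geometry.shape, dtype=np.int16),
            geometry=iso2_geometry,
            label_names={},
        )
        with caplog.at_level("WARNING"):
            assert assign_region(np.array([[1, 1, 1]]), rois, 10.0) == UNASSIGNED


class TestOccupancy:
    def test_bounds_and_degenerate_cases(self, iso2_geometry):
        cells = np.zeros(iso2_geometry.shape, dtype=np.int32)
        roi = np.zeros(iso2_geometry.shape, dtype=bool)
        roi[:4] = True
        assert occupancy(cells, roi) == 0.0
        cells[:4] = 1
        assert occupancy(cells, roi) == 1.0
        with pytest.raises(ValueError, match="empty ROI"):
            occupancy(cells, np.zeros(iso2_geometry.shape, dtype=bool))


class TestScaleBehavior:
    def test_doubling_voxel_size_scales_physical_not_solidity(self):
        vox = _cross_19() + 8
        for scale, expect_vol in ((1.0, 19.0), (2.0, 8 * 19.0)):
            g = StackGeometry(voxel_size_um=(scale,) * 3, shape=(16, 16, 16))
            arr = np.zeros(g.shape, dtype=np.int32)
            arr[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
            df = measure_cells(LabelVolume.from_array(arr, g))
            assert df.loc[0, "volume_um3"] == pytest.approx(expect_vol)
            assert df.loc[0, "solidity"] == pytest.approx(19 / 63)
        r1 = equiv_radius(19.0)
        r2 = equiv_radius(8 * 19.0)
        assert r2 == pytest.approx(2 * r1)


class TestSummarize:
    def _measure(self, iso2_geometry):
        arr = np.zeros(iso2_geometry.shape, dtype=np.int32)
        arr[2:4, 2:4, 2:4] = 1
        arr[10:13, 10:13, 10:13] = 2
        rois = np.zeros(iso2_geometry.shape, dtype=np.int16)
        rois[2:4, 2:4, 2:4] = 1
        roi_lv = LabelVolume(labels=rois, geometry=iso2_geometry, label_names={1: "ed"})
        return measure_cells(
            LabelVolume.from_array(arr, iso2_geometry), roi_lv, max_distance_um=5.0
        )

    def test_region_rows_and_all_row(self, iso2_geometry):
        df = self._measure(iso2_geometry)
        summary = summarize(df)
        regions = list(summary["region"])
        assert regions == ["ed", UNASSIGNED, "All"]
        all_row = summary[summary.region == "All"].iloc[0]
        assert all_row.n_cells == 2
        assert all_row.solidity_mean == pytest.approx(df.solidity.mean())
        assert all_row.volume_sd_um3 == pytest.approx(df.volume_um3.std(ddof=1))
        # counts: region rows + unassigned = All
        assert summary[summary.region != "All"].n_cells.sum() == all_row.n_cells

    def test_single_cell_sd_flagged(self, iso2_geometry):
        df = self._measure(iso2_geometry)
        one = summarize(df[df.region == "ed"])
        row = one[one.region == "ed"].iloc[0]
        assert row.n_cells == 1
        assert row.solidity_sd == 0.0
        assert not row.sd_defined

    def test_empty_input(self):
        import pandas as pd

        summary = summarize(pd.DataFrame(columns=["region", "solidity", "volume_um3", "equiv_radius_um"]))
        assert list(summary["region"]) == ["All"]
        assert summary.iloc[0].n_cells == 0
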