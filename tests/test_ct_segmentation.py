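"""Segmentation: region growing, refinement, airway handling, lung splitting."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from lungquant import (
    AirwaySegment,
    CtVolume,
    SegmentationMask,
    branch_diameter_map,
    exclude_large_airways,
    extract_airways,
    refine_mask,
    seeded_region_grow,
    split_left_right,
)
from lungquant.errors import DataError, SeedOutOfBoundsError, SplitFailedError


def bfs_flood_fill(hu: np.ndarray, seed, low, high) -> np.ndarray:
    """Independent oracle: breadth-first face-connected flood fill."""
    in_range = (hu >= low) & (hu <= high)
    out = np.zeros(hu.shape, dtype=bool)
    if not in_range[seed]:
        return out
    queue = deque([seed])
    out[seed] = True
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = (z + dz, y + dy, x + dx)
            if all(0 <= n[i] < hu.shape[i] for i in range(3)):
                if in_range[n] and not out[n]:
                    out[n] = True
                    queue.append(n)
    return out


class TestSeededRegionGrow:
    def test_uniform_block_fully_grown(self):
        vol = CtVolume(np.full((3, 3, 3), -800.0), 35.0)
        mask = seeded_region_grow(vol, (1, 1, 1), -1000, -150)
        assert mask.voxel_count == 27

    def test_growth_stops_at_out_of_range_voxel(self):
        hu = np.array([[[-800.0, -800.0, 0.0, -800.0, -800.0]]])
        vol = CtVolume(hu, 35.0)
        mask = seeded_region_grow(vol, (0, 0, 0), -1000, -150)
        expected = np.zeros_like(hu, dtype=bool)
        expected[0, 0, :2] = True
        assert np.array_equal(mask.voxels, expected)

    def test_seed_out_of_hu_range_gives_empty_mask(self):
        vol = CtVolume(np.zeros((2, 2, 2)), 35.0)
        assert seeded_region_grow(vol, (0, 0, 0), -1000, -150).voxel_count == 0

    def test_seed_out_of_bounds_raises(self):
        vol = CtVolume(np.zeros((2, 2, 2)), 35.0)
        with pytest.raises(SeedOutOfBoundsError):
            seeded_region_grow(vol, (5, 0, 0), -1000, -150)

    def test_non_finite_seed_raises(self):
        hu = np.zeros((2, 2, 2))
        hu[0, 0, 0] = np.nan
        with pytest.raises(DataError):
            seeded_region_grow(CtVolume(hu, 35.0), (0, 0, 0), -1000, -150)

    def test_inverted_window_raises(self):
        vol = CtVolume(np.zeros((2, 2, 2)), 35.0)
        with pytest.raises(DataError):
            seeded_region_grow(vol, (0, 0, 0), -150, -1000)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_bfs_oracle_on_random_grids(self, trial):
        rng = np.random.default_rng(1000 + trial)
        hu = rng.uniform(-1000, 200, size=(8, 8, 8))
        seed = tuple(rng.integers(0, 8, size=3))
        vol = CtVolume(hu, 35.0)
        mask = seeded_region_grow(vol, seed, -1000, -150)
        assert np.array_equal(mask.voxels, bfs_flood_fill(hu, seed, -1000, -150))

    def test_idempotent_under_reseeding(self, rng):
        hu = rng.uniform(-1000, 200, size=(8, 8, 8))
        vol = CtVolume(hu, 35.0)
        mask = seeded_region_grow(vol, (4, 4, 4), -1000, -150)
        if mask.voxel_count == 0:
            pytest.skip("seed landed out of range")
        for new_seed in map(tuple, np.argwhere(mask.voxels)[::7]):
            again = seeded_region_grow(vol, new_seed, -1000, -150)
            assert np.array_equal(again.voxels, mask.voxels)


class TestRefineMask:
    def test_fills_interior_hole(self):
        cube = np.zeros((7, 7, 7), dtype=bool)
        cube[1:6, 1:6, 1:6] = True
        cube[3, 3, 3] = False
        out = refine_mask(SegmentationMask(cube), 0, 0, True, 0)
        assert out.voxels[3, 3, 3]
        assert out.voxel_count == 125

    def test_all_zero_radii_is_identity(self, rng):
        mask = SegmentationMask(rng.random((6, 6, 6)) > 0.5)
        out = refine_mask(mask, 0, 0, False, 0)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_unit_dilation_gives_face_connected_ball(self):
        single = np.zeros((5, 5, 5), dtype=bool)
        single[2, 2, 2] = True
        out = refine_mask(SegmentationMask(single), grow_r=1, shrink_r=0,
                          fill_holes=False, smooth_r=0)
        assert out.voxel_count == 7  # centre + 6 face neighbours

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            refine_mask(SegmentationMask(np.ones((2, 2, 2), bool)), grow_r=-1)


def _air_cylinder(radius_vx: float, length: int = 40, edge_um: float = 35.0) -> CtVolume:
    """Axis-aligned air cylinder (HU -1000) in soft tissue (HU 0)."""
    size = int(2 * radius_vx + 9)
    hu = np.zeros((length, size, size))
    yy, xx = np.ogrid[0:size, 0:size]
    c = size // 2
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius_vx ** 2
    hu[:, disc] = -1000.0
    return CtVolume(hu, edge_um)


class TestAirways:
    def test_cylinder_centerline_diameter(self):
        vol = _air_cylinder(3.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        c = vol.shape[1] // 2
        aw = extract_airways(vol, lung, (20, c, c), air_hu_max=-900)
        centreline = aw.local_diameter_um[20, c, c]
        # analytic inscribed diameter 2 * r * edge = 210 um, +-1 voxel
        assert abs(centreline - 210.0) <= 35.0
        # cross-check every voxel against the distance-transform oracle
        edt = ndimage.distance_transform_edt(aw.voxels)
        expected = np.where(aw.voxels, (2 * edt - 1) * 35.0, 0.0)
        assert np.allclose(aw.local_diameter_um, expected)

    def test_single_voxel_tube_measures_one_voxel_edge(self):
        hu = np.zeros((1, 3, 3))
        hu[0, 1, 1] = -1000.0
        vol = CtVolume(hu, 35.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        aw = extract_airways(vol, lung, (0, 1, 1), air_hu_max=-900)
        assert aw.local_diameter_um[0, 1, 1] == pytest.approx(35.0)

    def test_small_cylinder_below_cutoff(self):
        vol = _air_cylinder(2.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        c = vol.shape[1] // 2
        aw = extract_airways(vol, lung, (20, c, c), air_hu_max=-900)
        assert aw.local_diameter_um[aw.voxels].max() < 200.0

    def test_diameter_never_below_voxel_edge(self):
        vol = _air_cylinder(3.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        c = vol.shape[1] // 2
        aw = extract_airways(vol, lung, (20, c, c), air_hu_max=-900)
        assert aw.local_diameter_um[aw.voxels].min() >= 35.0 - 1e-9

    def test_seed_not_air_raises(self):
        vol = _air_cylinder(2.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        with pytest.raises(DataError):
            extract_airways(vol, lung, (0, 0, 0), air_hu_max=-900)


class TestExcludeLargeAirways:
    @pytest.fixture()
    def wide_airway(self):
        vol = _air_cylinder(3.5)  # inscribed diameter ~217 um at 35 um pitch
        lung = SegmentationMask(np.ones(vol.shape, bool))
        c = vol.shape[1] // 2
        return lung, extract_airways(vol, lung, (20, c, c), air_hu_max=-900)

    def test_wide_branch_removed(self, wide_airway):
        lung, aw = wide_airway
        out = exclude_large_airways(lung, aw, 200.0)
        assert not (out.voxels & aw.voxels).any()

    def test_210um_branch_removed_at_fine_pitch(self):
        # a 210-um-diameter lumen sampled at 10 um, where rasterization error
        # is far below the 200-um cutoff margin
        vol = _air_cylinder(10.5, length=30, edge_um=10.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        c = vol.shape[1] // 2
        aw = extract_airways(vol, lung, (15, c, c), air_hu_max=-900)
        out = exclude_large_airways(lung, aw, 200.0)
        assert not (out.voxels & aw.voxels).any()

    def test_narrow_branch_kept(self):
        vol = _air_cylinder(2.0)
        lung = SegmentationMask(np.ones(vol.shape, bool))
        c = vol.shape[1] // 2
        aw = extract_airways(vol, lung, (20, c, c), air_hu_max=-900)
        out = exclude_large_airways(lung, aw, 200.0)
        assert np.array_equal(out.voxels, lung.voxels)

    def test_zero_cutoff_removes_all_airway_voxels(self, wide_airway):
        lung, aw = wide_airway
        out = exclude_large_airways(lung, aw, 0.0)
        assert not (out.voxels & aw.voxels).any()

    def test_never_adds_voxels(self, wide_airway):
        lung, aw = wide_airway
        out = exclude_large_airways(lung, aw, 200.0)
        assert not (out.voxels & ~lung.voxels).any()

    def test_branch_map_covers_lumen(self, wide_airway):
        _, aw = wide_airway
        bd = branch_diameter_map(aw)
        assert (bd[aw.voxels] > 0).all()
        assert (bd[~aw.voxels] == 0).all()


def _two_ellipsoid_lung(shift=0):
    mask = np.zeros((20, 24, 40), dtype=bool)
    zz, yy, xx = np.ogrid[0:20, 0:24, 0:40]
    for cx in (10 + shift, 30 + shift):
        mask |= ((zz - 10) / 8) ** 2 + ((yy - 12) / 9) ** 2 + ((xx - cx) / 6) ** 2 <= 1
    return mask


def _midline_airway(shape=(20, 24, 40)):
    aw = np.zeros(shape, dtype=bool)
    aw[2:10, 11:13, 19:21] = True
    diam = np.where(aw, 70.0, 0.0)
    return AirwaySegment(aw, diam)


class TestSplitLeftRight:
    def test_disjoint_components_assigned_by_centroid(self):
        lung = SegmentationMask(_two_ellipsoid_lung())
        left, right = split_left_right(lung, _midline_airway())
        assert left.voxels.any() and right.voxels.any()
        assert np.argwhere(left.voxels)[:, 2].max() < 20
        assert np.argwhere(right.voxels)[:, 2].min() > 19

    def test_union_and_disjointness(self):
        lung = SegmentationMask(_two_ellipsoid_lung())
        left, right = split_left_right(lung, _midline_airway())
        assert not (left.voxels & right.voxels).any()
        assert np.array_equal(left.voxels | right.voxels, lung.voxels)

    def test_mirror_symmetric_lungs_split_evenly(self):
        lung = SegmentationMask(_two_ellipsoid_lung())
        left, right = split_left_right(lung, _midline_airway())
        assert left.voxel_count == right.voxel_count

    def test_bridged_lungs_need_user_plane(self):
        bridged = _two_ellipsoid_lung()
        bridged[9:11, 11:13, :] = True  # residual air bridge
        lung = SegmentationMask(bridged)
        with pytest.raises(SplitFailedError):
            split_left_right(lung, _midline_airway())

    def test_user_plane_partitions_by_side(self):
        bridged = _two_ellipsoid_lung()
        bridged[9:11, 11:13, :] = True
        lung = SegmentationMask(bridged)
        plane = ((0.0, 0.0, 20.0 * 35.0), (0.0, 0.0, 1.0))  # sagittal at x=20
        left, right = split_left_right(lung, _midline_airway(), plane, 35.0)
        idx_left = np.argwhere(left.voxels)
        idx_right = np.argwhere(right.voxels)
        assert idx_left[:, 2].max() < 20
        assert idx_right[:, 2].min() >= 20
        assert np.array_equal(left.voxels | right.voxels, lung.voxels)


def test_phantom_segmentation_recovers_lung_volume(segmented_ct_phantom):
    """End-to-end: phantom -> segmentation recovers true volume within 5%."""
    volume, truth, seg = segmented_ct_phantom
    err = abs(seg.whole_lung.voxel_count - truth.lung_voxels) / truth.lung_voxels
    assert err <= 0.05
    assert seg.split_status == "ok"
    assert not (seg.left_lung.voxels & seg.right_lung.voxels).any()
    assert np.array_equal(
        seg.left_lung.voxels | seg.right_lung.voxels, seg.whole_lung.voxels
    )
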