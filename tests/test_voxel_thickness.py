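"""Ray sets, single-ray runs, and the voxel thickness encoder vs its oracle."""

import math

import numpy as np
import pytest

import cuticlemap as cm
from cuticlemap.voxel_thickness import SimilarityRule, VoxelThicknessConfig


def _min_pairwise_angle_deg(dirs: np.ndarray) -> float:
    dots = dirs @ dirs.T
    np.fill_diagonal(dots, -1.0)
    return math.degrees(math.acos(float(np.clip(dots.max(), -1.0, 1.0))))


class TestRaySets:
    def test_six_directions_are_the_axes(self):
        dirs = cm.make_ray_set(6).directions
        expect = {(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)}
        assert {tuple(int(round(c)) for c in d) for d in dirs} == expect

    def test_26_neighbour_set_closed_under_negation(self):
        rs = cm.make_ray_set(26)
        assert len(rs) == 26
        for d in rs.directions:
            assert np.any(np.all(np.abs(rs.directions + d) < 1e-9, axis=1))

    def test_fibonacci_sets_get_denser_with_count(self):
        a98 = _min_pairwise_angle_deg(cm.make_ray_set(98).directions)
        a200 = _min_pairwise_angle_deg(cm.make_ray_set(200).directions)
        assert a98 >= a200

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError):
            cm.make_ray_set(5)


class TestRayRunLength:
    def test_isolated_voxel_runs_one_in_any_direction(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        m = cm.SegmentationMask(mask)
        for d in cm.make_ray_set(26).directions:
            assert cm.ray_run_length(None, m, (4, 4, 4), d, rmax=90) == 1

    def test_solid_body_saturates_at_rmax(self):
        m = cm.SegmentationMask(np.ones((40, 40, 40), bool))
        assert cm.ray_run_length(None, m, (20, 20, 20), (1, 0, 0), rmax=15) == 15

    def test_mid_wall_slab_run_counts_origin_plus_remaining_wall(self, small_slab):
        _, _, mask, _ = small_slab
        zs = np.flatnonzero(mask.data.any(axis=(1, 2)))
        mid = zs[len(zs) // 2]  # centre of a 5-voxel wall
        run = cm.ray_run_length(None, mask, (mid, 16, 16), (1, 0, 0), rmax=90)
        assert run == 3

    def test_background_origin_returns_zero(self, small_slab):
        _, _, mask, _ = small_slab
        assert cm.ray_run_length(None, mask, (0, 0, 0), (1, 0, 0)) == 0

    def test_origin_outside_grid_raises(self, small_slab):
        _, _, mask, _ = small_slab
        with pytest.raises(IndexError):
            cm.ray_run_length(None, mask, (-1, 0, 0), (1, 0, 0))


class TestEncoder:
    def test_empty_mask_encodes_all_zero(self):
        m = cm.SegmentationMask(np.zeros((8, 8, 8), bool))
        f = cm.encode_thickness_volume(None, m, VoxelThicknessConfig(rmax=10))
        assert f.data.max() == 0

    def test_thin_slab_saturates_through_in_plane_rays(self):
        # lateral extent >> rmax: in-plane rays saturate the encoding
        spec = cm.PhantomSpec(kind="slab", grid_shape=(11, 60, 60), wall_thickness=5)
        _, mask, _ = cm.make_phantom(spec)
        f = cm.encode_thickness_volume(None, mask, VoxelThicknessConfig(rmax=20))
        zs = np.flatnonzero(mask.data.any(axis=(1, 2)))
        mid = zs[len(zs) // 2]
        interior = f.data[mid, 25:36, 25:36]
        assert np.all(interior == 20)

    def test_range_invariant_and_foreground_at_least_one(self, small_shell):
        _, _, mask, _ = small_shell
        f = cm.encode_thickness_volume(None, mask, VoxelThicknessConfig(rmax=30))
        assert f.data.min() >= 0 and f.data.max() <= 30
        assert np.all(f.data[mask.data] >= 1)
        assert np.all(f.data[~mask.data] == 0)

    def test_more_rays_never_decrease_the_encoding(self, small_shell):
        _, _, mask, _ = small_shell
        f6 = cm.encode_thickness_volume(None, mask, VoxelThicknessConfig(rmax=30, n_directions=6))
        f26 = cm.encode_thickness_volume(None, mask, VoxelThicknessConfig(rmax=30, n_directions=26))
        assert np.all(f26.data >= f6.data)

    def test_rotating_the_grid_permutes_the_encoding(self, small_slab):
        _, _, mask, _ = small_slab
        cfg = VoxelThicknessConfig(rmax=25)
        f = cm.encode_thickness_volume(None, mask, cfg)
        rot = cm.SegmentationMask(np.rot90(mask.data, axes=(0, 1)).copy())
        frot = cm.encode_thickness_volume(None, rot, cfg)
        assert np.array_equal(frot.data, np.rot90(f.data, axes=(0, 1)))

    def test_gray_tol_mode_on_clean_phantom_matches_mask_mode(self, small_slab):
        spec, vol, mask, _ = small_slab
        cfg_g = VoxelThicknessConfig(rmax=20, rule=SimilarityRule(mode="gray_tol", tol=10.0))
        cfg_m = VoxelThicknessConfig(rmax=20)
        fg_field = cm.encode_thickness_volume(vol, mask, cfg_g)
        fm_field = cm.encode_thickness_volume(vol, mask, cfg_m)
        assert np.array_equal(fg_field.data, fm_field.data)


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture", ["small_slab", "small_shell", "small_capsule"])
    def test_optimised_encoder_equals_brute_force(self, fixture, request):
        _, vol, mask, _ = request.getfixturevalue(fixture)
        cfg = VoxelThicknessConfig(rmax=30)
        fast = cm.encode_thickness_volume(vol, mask, cfg)
        slow = cm.brute_force_encode(vol, mask, cfg)
        assert np.array_equal(fast.data, slow.data)

    def test_brute_force_single_voxel(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        f = cm.brute_force_encode(None, cm.SegmentationMask(mask), VoxelThicknessConfig(rmax=10))
        assert f.data.sum() == 1 and f.data[4, 4, 4] == 1

    def test_brute_force_rejects_oversize_grids(self):
        m = cm.SegmentationMask(np.zeros((65, 65, 65), bool))
        with pytest.raises(ValueError, match="limited"):
            cm.brute_force_encode(None, m)

    def test_gray_tol_equivalence_on_noisy_phantom(self):
        spec = cm.PhantomSpec(
            kind="slab", grid_shape=(16, 20, 20), wall_thickness=4, noise_sd=20.0, seed=2
        )
        vol, mask, _ = cm.make_phantom(spec)
        cfg = VoxelThicknessConfig(rmax=15, rule=SimilarityRule(mode="gray_tol", tol=30.0))
        fast = cm.encode_thickness_volume(vol, mask, cfg)
        slow = cm.brute_force_encode(vol, mask, cfg)
        assert np.array_equal(fast.data, slow.data)
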