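"""Phantom geometry, ground truth, and cohort generation."""

import math

import numpy as np
import pytest

import cuticlemap as cm


class TestSlab:
    def test_noise_free_slab_is_axis_aligned_plate(self, small_slab):
        spec, vol, mask, truth = small_slab
        zs = np.flatnonzero(mask.data.any(axis=(1, 2)))
        assert len(zs) == 5 and np.all(np.diff(zs) == 1)
        assert np.all(truth.true_thickness[mask.data] == 5.0)

    def test_rotated_slab_has_transmural_truth(self):
        spec = cm.PhantomSpec(
            kind="slab", grid_shape=(48, 48, 48), wall_thickness=8, rotation_deg=30
        )
        _, mask, truth = cm.make_phantom(spec)
        assert mask.foreground_count() > 0
        assert np.all(truth.true_thickness[mask.data] == 8.0)


class TestShell:
    def test_voxel_count_close_to_analytic_shell_volume(self):
        R, t = 30.0, 6.0
        spec = cm.PhantomSpec(
            kind="spherical_shell", grid_shape=(68, 68, 68), outer_radius=R, wall_thickness=t
        )
        _, mask, _ = cm.make_phantom(spec)
        analytic = 4.0 / 3.0 * math.pi * (R**3 - (R - t) ** 3)
        assert abs(mask.foreground_count() - analytic) / analytic < 0.05

    def test_exact_voxel_centre_count_matches_enumeration(self):
        # independent enumeration over integer centres, no vectorised geometry
        R, t = 12.0, 3.0
        spec = cm.PhantomSpec(
            kind="spherical_shell", grid_shape=(32, 32, 32), outer_radius=R, wall_thickness=t
        )
        _, mask, _ = cm.make_phantom(spec)
        c = 15.5
        n = 0
        for z in range(32):
            for y in range(32):
                for x in range(32):
                    r = math.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
                    if R - t < r <= R:
                        n += 1
        assert mask.foreground_count() == n


class TestCapsule:
    def test_ventral_wall_twice_dorsal_and_depth_fraction(self, small_capsule):
        spec, _, mask, truth = small_capsule
        lab = truth.region_labels.data
        tt = truth.true_thickness
        ventral = np.unique(tt[lab == 1])
        dorsal = np.unique(tt[lab == 2])
        assert len(ventral) == 1 and len(dorsal) == 1
        assert ventral[0] == 2.0 * dorsal[0]
        assert truth.true_DP / truth.true_CL == pytest.approx(0.25)

    def test_all_anatomy_regions_present(self, small_capsule):
        _, _, _, truth = small_capsule
        present = set(np.unique(truth.region_labels.data))
        assert {1, 2, 3, 4} <= present

    def test_brood_canal_thickness_decays_posteriorly(self, small_capsule):
        _, _, _, truth = small_capsule
        lab = truth.region_labels.data
        tt = truth.true_thickness
        zs = np.nonzero(lab == 3)[0]
        front = tt[(lab == 3)][zs < np.percentile(zs, 20)].mean()
        back = tt[(lab == 3)][zs > np.percentile(zs, 80)].mean()
        assert front > back

    def test_geometry_too_large_raises_margin_error(self):
        with pytest.raises(ValueError, match="margin|fit"):
            cm.make_phantom(
                cm.PhantomSpec(
                    kind="spherical_shell",
                    grid_shape=(20, 20, 20),
                    outer_radius=12,
                    wall_thickness=3,
                )
            )


class TestInvariants:
    @pytest.mark.parametrize("fixture", ["small_slab", "small_shell", "small_capsule"])
    def test_mask_truth_congruence(self, fixture, request):
        _, _, mask, truth = request.getfixturevalue(fixture)
        assert np.array_equal(truth.true_thickness > 0, mask.data)

    def test_reproducibility_bit_identical(self):
        spec = dict(kind="slab", grid_shape=(16, 20, 20), wall_thickness=4, noise_sd=5.0, seed=42)
        v1, m1, _ = cm.make_phantom(cm.PhantomSpec(**spec))
        v2, m2, _ = cm.make_phantom(cm.PhantomSpec(**spec))
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(m1.data, m2.data)

    def test_noise_does_not_move_the_mask(self):
        base = dict(kind="slab", grid_shape=(16, 20, 20), wall_thickness=4)
        _, clean, _ = cm.make_phantom(cm.PhantomSpec(**base, noise_sd=0.0))
        _, noisy, _ = cm.make_phantom(cm.PhantomSpec(**base, noise_sd=50.0, seed=9))
        assert np.array_equal(clean.data, noisy.data)


class TestCohorts:
    def test_perfect_correlation_is_exact(self):
        rec = cm.make_cohort(cm.MorphometricCohortSpec(n=30, rho=1.0, seed=3))
        r = cm.correlate(rec, "DP", "PL").r
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_moment_recovery_at_large_n(self):
        spec = cm.MorphometricCohortSpec(n=10_000, rho=0.5, seed=11)
        rec = cm.make_cohort(spec)
        dp = np.array([r.DP for r in rec])
        pl = np.array([r.PL for r in rec])
        la = np.array([r.LA for r in rec])
        assert abs(dp.mean() - spec.mean_DP) < 3 * spec.sd_DP
        assert abs(pl.mean() - spec.mean_PL) < 3 * spec.sd_PL
        assert abs(la.mean() - spec.mean_LA) < 3 * spec.sd_LA
        # much tighter in practice: within 5 standard errors
        assert abs(dp.mean() - spec.mean_DP) < 5 * spec.sd_DP / math.sqrt(spec.n)

    def test_small_cohort_all_positive_and_valid(self):
        rec = cm.make_cohort(cm.MorphometricCohortSpec(n=3, rho=0.0, seed=0))
        assert len(rec) == 3  # record validation enforces positivity, DP<=CL, LA<=PL

    def test_reproducible_given_seed(self):
        a = cm.make_cohort(cm.MorphometricCohortSpec(n=20, rho=0.7, seed=5))
        b = cm.make_cohort(cm.MorphometricCohortSpec(n=20, rho=0.7, seed=5))
        assert [(r.DP, r.PL, r.LA) for r in a] == [(r.DP, r.PL, r.LA) for r in b]

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            cm.MorphometricCohortSpec(n=10, rho=1.5)
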