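import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npctomo.align import (AngularWindow, DegenerateOverlapError, FscCurve,
                           WedgeMask, align_particle, average, constrained_cc,
                           exclude_at_limits, fsc, normalized_cc,
                           resolution_at, split_halves)
from npctomo.geometry import _lowpass
from npctomo.particles import new_particle_table
from npctomo.phantom import make_subtomograms
from npctomo.transforms import RigidTransform, apply_transform, \
    rotation_angle_deg
from npctomo.volume import Volume


class TestWedgeMask:
    def test_friedel_symmetry(self):
        grid = WedgeMask(-60, 60, (16, 16, 16)).grid
        # interior voxels: support(k) == support(-k)
        flipped = grid[::-1, ::-1, ::-1]
        inner = np.roll(flipped, 1, axis=(0, 1, 2))
        assert np.array_equal(grid[1:, 1:, 1:], inner[1:, 1:, 1:])

    def test_fraction_strictly_between_zero_and_one(self):
        w = WedgeMask(-60, 60, (16, 16, 16))
        assert 0.0 < w.fraction() < 1.0
        # ±60 of ±90 covers about 2/3 of the (kx, kz) angle range
        assert w.fraction() == pytest.approx(2 / 3, abs=0.05)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            WedgeMask(60, -60, (8, 8, 8))


class TestConstrainedCC:
    def test_self_is_one(self, smooth_blob):
        w = WedgeMask(-60, 60, smooth_blob.shape)
        assert constrained_cc(smooth_blob, smooth_blob, w, w) == \
            pytest.approx(1.0, abs=1e-6)

    def test_negation_is_minus_one(self, smooth_blob):
        assert constrained_cc(smooth_blob, -smooth_blob, None, None) == \
            pytest.approx(-1.0, abs=1e-6)

    def test_planted_transform_beats_distant_poses(self):
        # exhaustive small-grid oracle on a 20-voxel phantom
        n, c = 20, 10
        x, y, z = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
        ph = (np.exp(-((x - 2) ** 2 + y ** 2 + z ** 2) / 8)
              + 0.7 * np.exp(-(x ** 2 + (y + 3) ** 2 + (z - 2) ** 2) / 6)
              ).astype(np.float32)
        t_true = RigidTransform(14, 7, -10)
        particle = apply_transform(ph, t_true.inverse())
        w = WedgeMask(-60, 60, (n,) * 3)
        best = constrained_cc(ph, particle, None, w, t_true.inverse())
        for phi in range(-30, 31, 10):
            for theta in range(0, 21, 10):
                for psi in range(-30, 31, 10):
                    t = RigidTransform(phi, theta, psi).inverse()
                    if rotation_angle_deg(t, t_true.inverse()) < 10:
                        continue
                    assert constrained_cc(ph, particle, None, w, t) < best

    def test_degenerate_overlap_raises(self, smooth_blob):
        tiny = np.zeros(smooth_blob.shape, dtype=bool)
        tiny.flat[:4] = True
        with pytest.raises(DegenerateOverlapError):
            constrained_cc(smooth_blob, smooth_blob, tiny, tiny)


class TestAlignParticle:
    def test_planted_pose_recovery(self, smooth_blob):
        t_true = RigidTransform(5, 3, -4, (2, 0, -1))
        particle = apply_transform(smooth_blob, t_true)
        t, score, _ = align_particle(particle, smooth_blob,
                                     AngularWindow(8, 8, 8, 1), n_inner=3)
        assert rotation_angle_deg(t, t_true.inverse()) <= 1.0
        assert np.linalg.norm(t.shift - t_true.inverse().shift) <= 0.5

    def test_window_collapse_is_translation_only(self, smooth_blob):
        t_true = RigidTransform(0, 0, 0, (2.5, -1, 0))
        particle = apply_transform(smooth_blob, t_true)
        t, _, _ = align_particle(particle, smooth_blob,
                                 AngularWindow(0, 0, 0, 1), n_inner=2)
        assert rotation_angle_deg(t) == 0.0
        np.testing.assert_allclose(t.shift, t_true.inverse().shift, atol=0.2)

    def test_angle_outside_window_flags_limit(self, smooth_blob):
        t_true = RigidTransform(9, 0, 0)
        particle = apply_transform(smooth_blob, t_true)
        t, _, at_limit = align_particle(particle, smooth_blob,
                                        AngularWindow(4, 4, 4, 2), n_inner=2)
        assert at_limit

    def test_aligned_particle_not_flagged(self, smooth_blob):
        _, _, at_limit = align_particle(smooth_blob, smooth_blob,
                                        AngularWindow(4, 4, 4, 2), n_inner=2)
        assert not at_limit


class TestAverage:
    def test_identical_particles_average_to_particle(self, smooth_blob):
        avg = average([smooth_blob] * 4, normalize=False)
        np.testing.assert_allclose(avg.data, smooth_blob, atol=1e-4)

    def test_rotated_wedges_fill_fourier_space(self, small_phantom):
        from npctomo.align import coverage_fraction
        w = WedgeMask(-60, 60, (32,) * 3)
        single = coverage_fraction([RigidTransform()], w)
        rng = np.random.default_rng(0)
        transforms = [RigidTransform(*rng.uniform(-60, 60, 3))
                      for _ in range(6)]
        pooled = coverage_fraction(transforms, w)
        assert pooled < single

    def test_determinism(self, small_phantom):
        parts, truths, w = make_subtomograms(4, box=32, snr=0.5, seed=5,
                                             reference=small_phantom)
        a = average(parts, truths, [w] * 4)
        b = average(parts, truths, [w] * 4)
        assert np.array_equal(a.data, b.data)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average([])


class TestSplitHalves:
    def test_even_split(self):
        h1, h2 = split_halves(np.arange(10))
        assert len(h1) == len(h2) == 5
        assert set(h1) | set(h2) == set(range(10))
        assert set(h1) & set(h2) == set()

    def test_cross_mode_by_label(self):
        ids = np.arange(6)
        labels = ["native", "actd", "native", "actd", "native", "actd"]
        a, b = split_halves(ids, mode="cross", labels=labels)
        assert {frozenset(a), frozenset(b)} == \
            {frozenset({0, 2, 4}), frozenset({1, 3, 5})}

    def test_too_few(self):
        with pytest.raises(ValueError):
            split_halves([1])


class TestFsc:
    def test_self_correlation_is_one(self, smooth_blob):
        curve = fsc(smooth_blob, smooth_blob)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-6)

    def test_negation_is_minus_one(self, smooth_blob):
        curve = fsc(smooth_blob, -smooth_blob)
        np.testing.assert_allclose(curve.values, -1.0, atol=1e-6)

    def test_values_bounded(self):
        rng = np.random.default_rng(0)
        curve = fsc(rng.normal(size=(16,) * 3), rng.normal(size=(16,) * 3))
        assert np.all(curve.values <= 1.0) and np.all(curve.values >= -1.0)

    def test_shape_mismatch_rejected(self, smooth_blob):
        with pytest.raises(ValueError):
            fsc(smooth_blob, smooth_blob[:16])

    def test_band_limited_resolution(self):
        # two noisy copies of a 30 A band-limited volume cross 0.5 near 30 A
        rng = np.random.default_rng(1)
        vox = 6.6
        base = _lowpass(rng.normal(size=(48,) * 3), vox, 30.0)
        base /= base.std()
        a = base + 1.0 * rng.normal(size=base.shape)
        b = base + 1.0 * rng.normal(size=base.shape)
        res = resolution_at(fsc(a, b, voxel_size=vox), 0.5)
        shell = 1.0 / (48 * vox)
        lo = 1.0 / (1.0 / 30 + 2 * shell)
        hi = 1.0 / (1.0 / 30 - 2 * shell)
        assert lo <= res <= hi

    def test_no_crossing_flag(self, smooth_blob):
        res, flag = resolution_at(fsc(smooth_blob, smooth_blob, voxel_size=4),
                                  0.5, return_flag=True)
        assert flag and res == pytest.approx(8.0)


class TestExcludeAtLimits:
    def test_counting_and_reasons(self):
        table = new_particle_table(10)
        table["at_window_limit"] = [True, False, True, False, True] + [False] * 5
        out = exclude_at_limits(table)
        assert out["keep"].sum() == 7
        assert (out.loc[~out["keep"], "reason"] == "angle_at_limit").all()
        # untouched rows
        assert (out.loc[out["keep"], "reason"] == "").all()

    def test_no_flags_is_identity(self):
        table = new_particle_table(4)
        table["at_window_limit"] = False
        out = exclude_at_limits(table)
        assert out["keep"].all()


class TestResolutionImprovesWithN:
    def test_halfset_resolution_non_increasing(self, small_phantom):
        # median over seeds: resolution at 0.5 does not worsen as the
        # particle count doubles 8 -> 16 -> 32
        vox = small_phantom.voxel_size
        res = {8: [], 16: [], 32: []}
        for seed in range(3):
            parts, truths, w = make_subtomograms(32, box=32, snr=0.5,
                                                 seed=seed,
                                                 reference=small_phantom)
            for n in (8, 16, 32):
                h1 = average(parts[:n:2], truths[:n:2], [w] * (n // 2))
                h2 = average(parts[1:n:2], truths[1:n:2], [w] * (n // 2))
                res[n].append(resolution_at(fsc(h1, h2, voxel_size=vox), 0.5))
        assert np.median(res[16]) <= np.median(res[8]) + 1e-9
        assert np.median(res[32]) <= np.median(res[16]) + 1e-9
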