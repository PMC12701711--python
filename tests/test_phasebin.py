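import numpy as np
import pytest

from artifactlab.core import LungMask, Volume
from artifactlab.phasebin import (
    AdmissibilityCheck,
    PhaseBinningParams,
    StackMask,
    blend,
    build_stack_mask,
    check_admissibility,
    derive_pb_mask,
    feather_stack_mask,
    infuse_phase_binning,
    shift_secondary,
)


def _lung_with_extent(z_lo, z_hi, n=64):
    m = np.zeros((8, 8, n), np.uint8)
    m[2:6, 2:6, z_lo : z_hi + 1] = 1
    return LungMask(m)


class TestStackPlacement:
    def test_single_stack_domain_and_mass(self):
        lung = _lung_with_extent(10, 50)
        params = PhaseBinningParams(h=4, n_stacks=1, seed=0)
        sm = build_stack_mask(64, params, lung)
        (start, h), = sm.stacks
        assert 10 <= start <= 26  # z_mid = 30, start + h <= 30
        assert sm.binary_profile.sum() == 4

    def test_determinism(self):
        lung = _lung_with_extent(5, 55)
        params = PhaseBinningParams(h=8, n_stacks=2, seed=11)
        a = build_stack_mask(64, params, lung)
        b = build_stack_mask(64, params, lung)
        assert a.stacks == b.stacks

    def test_monte_carlo_inferior_half(self):
        """1000 draws: every stack slice stays at or below the lung z midpoint."""
        lung = _lung_with_extent(12, 52)
        z_mid = (12 + 52) // 2
        for seed in range(1000):
            sm = build_stack_mask(
                64, PhaseBinningParams(h=5, n_stacks=1, seed=seed), lung
            )
            slices = np.nonzero(sm.binary_profile)[0]
            assert slices.max() <= z_mid and slices.min() >= 12

    def test_unfittable_raises(self):
        lung = _lung_with_extent(10, 14)  # midpoint 12: no room for h=8
        with pytest.raises(ValueError):
            build_stack_mask(64, PhaseBinningParams(h=8, n_stacks=1), lung)


class TestFeather:
    def _stack(self, n=40, start=15, h=6):
        profile = np.zeros(n)
        profile[start : start + h] = 1
        return StackMask(profile, profile.copy(), [(start, h)])

    def test_small_sigma_approximates_binary(self):
        sm = self._stack()
        out = feather_stack_mask(sm, 1e-3)
        np.testing.assert_allclose(out.feathered_profile, sm.binary_profile,
                                   atol=1e-6)

    def test_range_and_peak(self):
        out = feather_stack_mask(self._stack(), 2.0)
        assert out.feathered_profile.min() >= 0
        assert out.feathered_profile.max() == pytest.approx(1.0)

    def test_support_widens_with_sigma(self):
        s1 = feather_stack_mask(self._stack(), 1.0)
        s3 = feather_stack_mask(self._stack(), 3.0)
        assert (s3.feathered_profile > 0.05).sum() > (s1.feathered_profile > 0.05).sum()


class TestShift:
    def _ramp(self, n=24):
        x = np.arange(n, dtype=float)
        data = np.tile(x[:, None, None], (1, n, n)) / n
        return Volume(data, intensity_domain="normalized")

    def test_zero_shift_identity(self):
        v = self._ramp()
        sm = StackMask(np.zeros(24), np.zeros(24), [(5, 4)])
        out = shift_secondary(v, sm, 0, seed=1)
        np.testing.assert_array_equal(out.data, v.data)

    def test_locality_outside_stacks(self, rng):
        v = Volume(rng.uniform(0, 1, (16, 16, 32)), intensity_domain="normalized")
        sm = StackMask(np.zeros(32), np.zeros(32), [(10, 5)])
        out = shift_secondary(v, sm, 2, seed=3)
        outside = np.ones(32, bool)
        outside[10:15] = False
        np.testing.assert_array_equal(out.data[:, :, outside], v.data[:, :, outside])

    def test_ramp_shift_matches_index_arithmetic(self):
        v = self._ramp()
        sm = StackMask(np.zeros(24), np.zeros(24), [(8, 3)])
        rng = np.random.default_rng(5)
        out = shift_secondary(v, sm, 1, rng=rng)
        # redraw the same offsets to know what was applied
        rng2 = np.random.default_rng(5)
        dx, dy = (int(rng2.integers(-1, 2)) for _ in range(2))
        # interior voxels (edge-replication-free zone)
        inner = slice(2, -2)
        expected = v.data[inner, inner, 8:11]
        got = out.data
        shifted = got[
            slice(2 + dx, got.shape[0] - 2 + dx),
            slice(2 + dy, got.shape[1] - 2 + dy), 8:11,
        ]
        np.testing.assert_allclose(shifted, expected, atol=1e-12)

    def test_negative_shift_rejected(self):
        v = self._ramp()
        sm = StackMask(np.zeros(24), np.zeros(24), [(5, 3)])
        with pytest.raises(ValueError):
            shift_secondary(v, sm, -1)


class TestAdmissibility:
    def _pair(self, delta):
        I = Volume(np.full((6, 6, 10), 0.5), intensity_domain="normalized")
        Ig = Volume(np.clip(I.data + delta, 0, 1), intensity_domain="normalized")
        profile = np.zeros(10)
        profile[3:6] = 1.0
        sm = StackMask(profile, profile.copy(), [(3, 3)])
        return I, Ig, sm

    def test_all_negative_admissible(self):
        I, Ig, sm = self._pair(+0.2)  # I - Ig < 0 inside stacks
        assert check_admissibility(I, Ig, sm).admissible

    def test_equal_images_not_admissible(self):
        I, Ig, sm = self._pair(0.0)
        chk = check_admissibility(I, Ig, sm)
        assert chk.n_nonpositive == chk.n_nonnegative
        assert not chk.admissible

    def test_zero_counts_on_both_sides(self):
        chk = AdmissibilityCheck(np.array([-1.0, -1.0, 0.0, 1.0]), 3, 2)
        assert chk.admissible

    def test_brute_force_voxel_loop_oracle(self, rng):
        """Vectorized counts match an explicit voxel loop on small grids."""
        for trial in range(5):
            shape = (6, 7, 9)
            I = Volume(rng.uniform(0, 1, shape), intensity_domain="normalized")
            Ig = Volume(rng.uniform(0, 1, shape), intensity_domain="normalized")
            w = rng.uniform(0, 1, shape[2])
            sm = StackMask((w > 0.5).astype(float), w, [(0, shape[2])])
            chk = check_admissibility(I, Ig, sm)
            n_le = n_ge = 0
            for x in range(shape[0]):
                for y in range(shape[1]):
                    for z in range(shape[2]):
                        c = w[z] * (I.data[x, y, z] - Ig.data[x, y, z])
                        n_le += c <= 0
                        n_ge += c >= 0
            assert (chk.n_nonpositive, chk.n_nonnegative) == (n_le, n_ge)


class TestBlend:
    def test_zero_mask_returns_primary(self, rng):
        I = Volume(rng.uniform(0, 1, (8, 8, 12)), intensity_domain="normalized")
        Ig = Volume(rng.uniform(0, 1, (8, 8, 12)), intensity_domain="normalized")
        sm = StackMask(np.zeros(12), np.zeros(12), [])
        np.testing.assert_array_equal(blend(I, Ig, sm).data, I.data)

    def test_unit_mask_slice_copies_secondary(self, rng):
        I = Volume(rng.uniform(0, 1, (8, 8, 12)), intensity_domain="normalized")
        Ig = Volume(rng.uniform(0, 1, (8, 8, 12)), intensity_domain="normalized")
        w = np.zeros(12)
        w[4] = 1.0
        sm = StackMask(w.copy(), w, [(4, 1)])
        out = blend(I, Ig, sm)
        np.testing.assert_array_equal(out.data[:, :, 4], Ig.data[:, :, 4])

    def test_convex_midpoint(self):
        I = Volume(np.full((4, 4, 4), 0.2), intensity_domain="normalized")
        Ig = Volume(np.full((4, 4, 4), 0.6), intensity_domain="normalized")
        w = np.full(4, 0.5)
        out = blend(I, Ig, StackMask(w, w, [(0, 4)]))
        np.testing.assert_allclose(out.data, 0.4)

    def test_convex_combination_bounds(self, rng):
        I = Volume(rng.uniform(0, 1, (8, 8, 16)), intensity_domain="normalized")
        Ig = Volume(rng.uniform(0, 1, (8, 8, 16)), intensity_domain="normalized")
        w = rng.uniform(0, 1, 16)
        out = blend(I, Ig, StackMask((w > 0.5).astype(float), w, [(0, 16)]))
        lo = np.minimum(I.data, Ig.data) - 1e-12
        hi = np.maximum(I.data, Ig.data) + 1e-12
        assert np.all(out.data >= lo) and np.all(out.data <= hi)


class TestDerivePBMask:
    def test_identical_images_empty_mask(self, rng):
        I = Volume(rng.uniform(0, 1, (16, 16, 16)), intensity_domain="normalized")
        params = PhaseBinningParams(sigma_g=1.0)
        mask = derive_pb_mask(I, I.copy(), params)
        assert not mask.data.any()

    def test_uniform_block_recovered(self):
        I = Volume(np.zeros((32, 32, 32)), intensity_domain="normalized")
        data = I.data.copy()
        data[5:25, 5:25, 5:25] = 0.5
        Ihat = Volume(data, intensity_domain="normalized")
        params = PhaseBinningParams(sigma_g=2.0, lambda0=0.05, r_close=0,
                                    min_component=1)
        mask = derive_pb_mask(I, Ihat, params)
        np.testing.assert_array_equal(mask.data > 0, data > 0)

    def test_speckle_removed_by_component_filter(self, rng):
        I = Volume(np.zeros((24, 24, 24)), intensity_domain="normalized")
        data = I.data.copy()
        # isolated super-threshold voxels on a sparse lattice
        data[::6, ::6, ::6] = 0.9
        Ihat = Volume(data, intensity_domain="normalized")
        params = PhaseBinningParams(sigma_g=1.0, lambda0=0.05, r_close=0,
                                    min_component=50)
        assert not derive_pb_mask(I, Ihat, params).data.any()

    def test_lambda_above_one_rejected(self):
        I = Volume(np.zeros((8, 8, 8)), intensity_domain="normalized")
        params = PhaseBinningParams(sigma_g=30.0, lambda0=0.05)
        with pytest.raises(ValueError):
            derive_pb_mask(I, I, params)


class TestInfusion:
    def test_secondary_equals_primary_rejected(self, norm_t00, lung_t00):
        # no in-plane shift: C is identically zero, so the strict majority
        # condition can never hold
        params = PhaseBinningParams(h=6, n_stacks=1, sigma_g=1.0,
                                    shift_intensity=0, seed=0)
        res = infuse_phase_binning(norm_t00, norm_t00, lung_t00, params)
        assert not res.accepted
        assert res.n_attempts == params.max_retries

    def test_t50_secondary_admissible(self, norm_t00, norm_t50, lung_t00):
        params = PhaseBinningParams(h=6, n_stacks=1, sigma_g=1.0,
                                    shift_intensity=0, seed=4)
        res = infuse_phase_binning(norm_t00, norm_t50, lung_t00, params)
        assert res.accepted and res.n_attempts == 1
        assert res.artifact_mask.phase_binning().any()

    def test_mask_confined_to_feathered_support(self, norm_t00, norm_t50, lung_t00):
        params = PhaseBinningParams(h=6, n_stacks=1, sigma_g=1.5,
                                    shift_intensity=0, seed=9)
        res = infuse_phase_binning(norm_t00, norm_t50, lung_t00, params)
        assert res.accepted
        support = res.stack_mask.feathered_profile > 0
        mask_slices = res.artifact_mask.any_artifact().any(axis=(0, 1))
        assert np.all(support[mask_slices])

    def test_full_pipeline_determinism(self, norm_t00, norm_t50, lung_t00):
        params = PhaseBinningParams(h=6, n_stacks=1, sigma_g=1.2,
                                    shift_intensity=1, seed=21)
        a = infuse_phase_binning(norm_t00, norm_t50, lung_t00, params)
        b = infuse_phase_binning(norm_t00, norm_t50, lung_t00, params)
        assert a.accepted == b.accepted
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.artifact_mask.data, b.artifact_mask.data)
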