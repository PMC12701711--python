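import numpy as np
import pytest

from artifactlab.core import Volume
from artifactlab.detect import (
    DEFAULT_LENGTHS,
    FitConfig,
    LabeledVolume,
    ThresholdProfile,
    consolidate,
    detect,
    dice_for_threshold,
    fit_thresholds,
    interval_difference,
    iter_windows,
    scan_intervals,
    segment_of,
)
from artifactlab.interp import InterpParams, Interval, infuse_interpolation, perturb_intervals


def _noisy_volume(rng, n_slices=40, side=12):
    return Volume(rng.uniform(0, 1, (side, side, n_slices)),
                  intensity_domain="normalized")


class TestIntervalDifference:
    def test_infused_interval_reproduces(self, rng):
        v = _noisy_volume(rng)
        out, _ = infuse_interpolation(v, [Interval(10, 15)])
        assert interval_difference(out, Interval(10, 15)) <= 1e-6

    def test_noise_floor_on_clean_phantom(self, norm_t00, lung_t00):
        """Non-interpolated intervals differ by far more than the epsilon
        detector threshold everywhere, and by > 0.05 inside the lungs
        (HU clipping at -1024 dampens the floor in pure-air slices)."""
        diffs = [
            interval_difference(norm_t00, Interval(z, z + 2))
            for z in range(norm_t00.n_slices - 2)
        ]
        assert min(diffs) > 10 * 1e-3
        z_lo, z_hi = lung_t00.z_extent()
        assert min(diffs[z_lo : z_hi - 2]) > 0.05


class TestSegmentOf:
    @pytest.mark.parametrize("z,expected", [(5, 0), (95, 9), (50, 5)])
    def test_deciles(self, z, expected):
        assert segment_of(z, 100, 10) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            segment_of(100, 100, 10)


class TestScan:
    def test_window_count(self, rng):
        v = _noisy_volume(rng, n_slices=10)
        assert len(list(iter_windows(10, (3, 4)))) == 8 + 7

    def test_noise_volume_zero_candidates(self, rng):
        v = _noisy_volume(rng)
        profile = ThresholdProfile.uniform(0.25)
        # uniform noise: max-abs interior difference is essentially always
        # far above 0.25 for 12x12 slices
        assert scan_intervals(v, profile) == []

    def test_all_subintervals_of_infused_interval_flagged(self, rng):
        v = _noisy_volume(rng)
        out, _ = infuse_interpolation(v, [Interval(10, 17)])
        cands = scan_intervals(out, ThresholdProfile.uniform(1e-3))
        expected = {
            (a, a + L - 1)
            for L in DEFAULT_LENGTHS for a in range(10, 18 - L + 1)
        }
        got = {(c.interval.z_start, c.interval.z_end) for c in cands}
        assert got == expected

    def test_candidate_set_monotone_in_threshold(self, rng):
        v = _noisy_volume(rng, n_slices=30)
        out, _ = infuse_interpolation(v, [Interval(5, 9)])
        small = {(c.interval.z_start, c.interval.z_end)
                 for c in scan_intervals(out, ThresholdProfile.uniform(0.01))}
        large = {(c.interval.z_start, c.interval.z_end)
                 for c in scan_intervals(out, ThresholdProfile.uniform(0.3))}
        assert small <= large


class TestConsolidate:
    def test_overlap_merge(self):
        assert consolidate([Interval(2, 4), Interval(3, 5)]) == [Interval(2, 5)]

    def test_containment_drop(self):
        assert consolidate([Interval(2, 4), Interval(2, 5)]) == [Interval(2, 5)]

    def test_disjoint_retained(self):
        out = consolidate([Interval(2, 4), Interval(8, 10)])
        assert out == [Interval(2, 4), Interval(8, 10)]

    def test_idempotence(self, rng):
        ivs = [Interval(int(a), int(a) + int(b))
               for a, b in zip(rng.integers(0, 50, 20), rng.integers(2, 8, 20))]
        once = consolidate(ivs)
        assert consolidate(once) == once


class TestDetect:
    def test_perfect_recovery_at_epsilon(self, rng):
        v = _noisy_volume(rng, n_slices=50)
        truth = [Interval(8, 13), Interval(30, 36)]
        out, mask = infuse_interpolation(v, truth)
        res = detect(out, ThresholdProfile.uniform(1e-3))
        assert res.intervals == truth

    def test_clean_noisy_phantom_no_detections(self, norm_t00):
        res = detect(norm_t00, ThresholdProfile.uniform(1e-3))
        assert res.intervals == []

    def test_order_independence_of_segments(self, rng):
        """The final detection is the same regardless of the order in which
        candidate windows are evaluated (set semantics)."""
        v = _noisy_volume(rng, n_slices=40)
        out, _ = infuse_interpolation(v, [Interval(12, 18)])
        cands = scan_intervals(out, ThresholdProfile.uniform(1e-3))
        forward = consolidate([c.interval for c in cands])
        backward = consolidate([c.interval for c in reversed(cands)])
        assert forward == backward

    def test_heuristic_matches_exhaustive_all_lengths(self, rng):
        """Lengths {3,4} + merging recover the same slice set as brute-force
        testing of every interval length up to n_slices - 2."""
        for trial in range(3):
            v = _noisy_volume(rng, n_slices=40)
            ivs = perturb_intervals(
                InterpParams(h=7, n_intervals=2, sigma_g=1.0, seed=trial), 40
            )
            out, _ = infuse_interpolation(v, ivs)
            eps = 1e-3
            res = detect(out, ThresholdProfile.uniform(eps))
            brute = [
                iv for iv in iter_windows(40, range(3, 39))
                if interval_difference(out, iv) < eps
            ]
            brute_final = consolidate(brute)
            brute_flags = np.zeros(40, bool)
            for iv in brute_final:
                brute_flags[iv.z_start : iv.z_end + 1] = True
            np.testing.assert_array_equal(res.slice_flags, brute_flags)


class TestFit:
    def _cases(self, n=6, n_slices=60):
        cases = []
        for seed in range(n):
            rng = np.random.default_rng(seed + 100)
            v = Volume(rng.uniform(0, 1, (12, 12, n_slices)),
                       intensity_domain="normalized")
            ivs = perturb_intervals(
                InterpParams(h=8, n_intervals=2, sigma_g=1.0, seed=seed), n_slices
            )
            out, mask = infuse_interpolation(v, ivs)
            cases.append(LabeledVolume.from_mask(out, mask))
        return cases

    def test_dice_arithmetic(self):
        from artifactlab.metrics import dice_from_counts

        assert dice_from_counts(2, 1, 1) == pytest.approx(2 / 3)

    def test_separated_world_fits_inside_bounds(self):
        cases = self._cases()
        res = fit_thresholds(cases, FitConfig(n_folds=3))
        assert all(0.2 < p < 0.3 for p in res.profile.thresholds)
        populated = [l for l in res.segment_loss if np.isfinite(l)]
        assert populated and max(populated) == 0.0

    def test_grid_and_brent_agree(self):
        cases = self._cases(4)
        grid = fit_thresholds(cases, FitConfig(n_folds=2, optimizer="grid"))
        brent = fit_thresholds(cases, FitConfig(n_folds=2, optimizer="brent"))
        # on a flat-zero objective both stay in bounds; losses agree
        for lg, lb in zip(grid.segment_loss, brent.segment_loss):
            if np.isfinite(lg) and np.isfinite(lb):
                assert lg == pytest.approx(lb, abs=1e-6)

    def test_fit_determinism(self):
        cases = self._cases(3)
        a = fit_thresholds(cases, FitConfig(n_folds=2))
        b = fit_thresholds(cases, FitConfig(n_folds=2))
        assert a.profile.thresholds == b.profile.thresholds

    def test_dice_for_threshold_requires_populated_segment(self):
        cases = self._cases(2)
        empty_seg = None
        for seg in range(10):
            if all(not c.truth_slices[
                slice(seg * 6, (seg + 1) * 6)
            ].any() for c in cases):
                empty_seg = seg
                break
        if empty_seg is not None:
            with pytest.raises(ValueError):
                dice_for_threshold(cases, empty_seg, 0.25)
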