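"""Generators: isoscapes, schedules, environments, tooth recording,
radiocarbon draws - all against closed-form or brute-force oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from toothtrack import synthetic
from toothtrack.recording import TOOTH_TIMINGS, ToothTiming, window_mean


class TestMakeIsoscape:
    def test_degenerate_constant_field(self):
        iso = synthetic.make_isoscape(shape=(10, 10), n_patches=0,
                                      ratio_range=(0.711, 0.711), seed=0)
        np.testing.assert_allclose(iso.mean_grid, 0.711)

    def test_same_seed_bit_identical(self):
        a = synthetic.make_isoscape(seed=42)
        b = synthetic.make_isoscape(seed=42)
        assert np.array_equal(a.mean_grid, b.mean_grid)
        assert np.array_equal(a.sd_grid, b.sd_grid)

    def test_different_seed_differs(self):
        a = synthetic.make_isoscape(seed=1)
        b = synthetic.make_isoscape(seed=2)
        assert not np.array_equal(a.mean_grid, b.mean_grid)

    def test_ratio_range_respected_exhaustive_scan(self):
        iso = synthetic.make_isoscape(shape=(32, 32), n_patches=3,
                                      ratio_range=(0.705, 0.718), seed=7)
        # brute-force scan of every cell
        for v in iso.mean_grid.ravel():
            assert 0.705 <= v <= 0.718

    def test_sd_layer_strictly_positive(self):
        iso = synthetic.make_isoscape(seed=3, sd_level=0.002)
        assert np.all(iso.sd_grid > 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            synthetic.make_isoscape(sd_level=0.0)
        with pytest.raises(ValueError):
            synthetic.make_isoscape(shape=(4, 4))
        with pytest.raises(ValueError):
            synthetic.make_isoscape(n_patches=-1)


class TestSchedule:
    def test_contiguity_enforced(self):
        camps = [(1.0, 1.0, 2000.0)]
        with pytest.raises(ValueError, match="contiguous"):
            synthetic.MovementSchedule(camps, [(0, 0.0, 10.0), (0, 20.0, 30.0)])

    def test_camp_index_validated(self):
        with pytest.raises(ValueError, match="out of range"):
            synthetic.MovementSchedule([(1.0, 1.0, 0.0)], [(3, 0.0, 10.0)])

    def test_seasonal_schedule_counts_moves(self):
        camps = [(0.0, 0.0, 0.0), (1.0, 1.0, 0.0)]
        sched = synthetic.make_seasonal_schedule(camps, moves_per_year=4, n_years=2)
        assert sched.n_relocations() == 7  # 8 stays -> 7 changes

    def test_yaml_round_trip(self, tmp_path):
        camps = [(0.0, 0.0, 1800.0), (5000.0, 0.0, 2400.0)]
        sched = synthetic.make_seasonal_schedule(camps, moves_per_year=4, n_years=1)
        p = tmp_path / "sched.yaml"
        sched.to_yaml(p)
        back = synthetic.MovementSchedule.from_yaml(p)
        assert back.camps == sched.camps
        assert back.occupancy == sched.occupancy


class TestSimulateEnvironment:
    def test_single_camp_zero_amplitude_all_constant(self, two_patch_isoscape):
        sched = synthetic.make_seasonal_schedule(
            [(4000.0, 4000.0, 2000.0)], moves_per_year=2, n_years=2)
        env = synthetic.simulate_environment(
            sched, two_patch_isoscape, d18O_params={"amplitude": 0.0})
        assert np.ptp(env.sr_ratio) == 0
        assert np.ptp(env.d18O) == 0
        assert np.ptp(env.d13C_enamel) == 0

    def test_d18O_seasonal_range_is_twice_amplitude(self, two_patch_isoscape):
        sched = synthetic.make_seasonal_schedule(
            [(4000.0, 4000.0, 2000.0)], moves_per_year=2, n_years=3)
        env = synthetic.simulate_environment(
            sched, two_patch_isoscape,
            d18O_params={"mean": -12.8, "amplitude": 2.45})
        assert np.ptp(env.d18O) == pytest.approx(4.9, abs=0.01)

    def test_sr_series_has_exactly_scheduled_jumps(self, two_patch_env):
        sched, env = two_patch_env
        n_jumps = int(np.sum(np.diff(env.sr_ratio) != 0))  # brute-force diff count
        assert n_jumps == sched.n_relocations()
        assert set(np.round(np.unique(env.sr_ratio), 6)) == {0.711, 0.713}

    def test_camp_outside_grid_names_camp(self, two_patch_isoscape):
        sched = synthetic.make_seasonal_schedule(
            [(4000.0, 4000.0, 2000.0), (1e7, 1e7, 2000.0)], 2, 1.0)
        with pytest.raises(ValueError, match="camp 1"):
            synthetic.simulate_environment(sched, two_patch_isoscape)


class TestRecordTooth:
    def _flat_env(self, value=0.7123, n_days=2200):
        t = np.arange(n_days, dtype=float)
        z = np.zeros(n_days)
        return synthetic.EnvironmentSeries(t, np.full(n_days, value), z, z, z + 1.0)

    def test_constant_environment_records_constant(self):
        env = self._flat_env()
        p = synthetic.record_tooth(env, TOOTH_TIMINGS["M2"], 90.0, 40, noise_sd=0.0)
        np.testing.assert_allclose(p.value, 0.7123, atol=1e-12)

    def test_noise_reproducible_for_seed(self):
        env = self._flat_env()
        a = synthetic.record_tooth(env, TOOTH_TIMINGS["M2"], 90.0, 40, 0.001, seed=5)
        b = synthetic.record_tooth(env, TOOTH_TIMINGS["M2"], 90.0, 40, 0.001, seed=5)
        np.testing.assert_array_equal(a.value, b.value)

    def test_step_response_is_rectangular_kernel_ramp(self):
        # a step at day t0 convolved with a rectangular window of width W
        # must come out as a linear ramp of temporal extent exactly W
        t = np.arange(2200, dtype=float)
        t0, lo, hi, W = 600.0, 0.710, 0.713, 120.0
        vals = np.where(t < t0, lo, hi)
        z = np.zeros(t.size)
        env = synthetic.EnvironmentSeries(t, vals, z, z, z)
        timing = TOOTH_TIMINGS["M1"]
        p = synthetic.record_tooth(env, timing, W, 400, noise_sd=0.0)
        ages = timing.age_at_distance(p.distance_mm)

        def closed_form(a):
            if a + W <= t0:
                return lo
            if a >= t0:
                return hi
            frac_hi = (a + W - t0) / W
            return lo + (hi - lo) * frac_hi

        expected = np.array([closed_form(a) for a in ages])
        np.testing.assert_allclose(p.value, expected, atol=2e-5)

    def test_sinusoid_attenuation_matches_sinc_and_quadrature(self):
        P, W, A = 365.0, 120.0, 2.0
        t = np.arange(2200, dtype=float)
        vals = A * np.sin(2 * np.pi * t / P)
        starts = np.array([700.0, 811.5, 923.0])
        got = window_mean(t, vals, starts, W)
        atten = abs(np.sin(np.pi * W / P) / (np.pi * W / P))
        for s, g in zip(starts, got):
            oracle, _ = quad(lambda x: A * np.sin(2 * np.pi * x / P) / W, s, s + W)
            assert g == pytest.approx(oracle, abs=1e-4)
        # recorded amplitude attenuated by |sinc|
        all_means = window_mean(t, vals, np.arange(400.0, 1400.0), W)
        assert np.max(np.abs(all_means)) == pytest.approx(A * atten, rel=1e-3)

    def test_recorder_is_linear_in_environment(self):
        rng = np.random.default_rng(3)
        t = np.arange(2200, dtype=float)
        v1 = rng.standard_normal(t.size).cumsum()
        v2 = rng.standard_normal(t.size).cumsum()
        z = np.zeros(t.size)
        timing = TOOTH_TIMINGS["M2"]

        def rec(v):
            env = synthetic.EnvironmentSeries(t, v, z, z, z)
            return synthetic.record_tooth(env, timing, 90.0, 50, 0.0).value

        a, b = 2.5, -0.7
        np.testing.assert_allclose(rec(a * v1 + b * v2), a * rec(v1) + b * rec(v2),
                                   rtol=1e-9, atol=1e-9)

    def test_insufficient_coverage_raises_with_requirement(self):
        env = self._flat_env(n_days=400)
        with pytest.raises(ValueError, match="cover"):
            synthetic.record_tooth(env, TOOTH_TIMINGS["M3"], 90.0, 40)

    def test_distances_decrease_in_age(self):
        env = self._flat_env()
        timing = TOOTH_TIMINGS["M2"]
        p = synthetic.record_tooth(env, timing, 90.0, 40)
        ages = timing.age_at_distance(p.distance_mm)
        assert np.all(np.diff(p.distance_mm) > 0)
        assert np.all(np.diff(ages) < 0)  # older enamel toward the apex


class TestToothTimings:
    def test_default_integration_spans(self):
        # published mineralization windows integrate ~1.9, 2.5, 2.8 years
        spans = {k: round(t.integration_years, 1) for k, t in TOOTH_TIMINGS.items()}
        assert spans == {"M1": 1.9, "M2": 2.5, "M3": 2.8}

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            ToothTiming("bad", 10.0, 1.0, 5.0, 1.0, 60.0)


class TestRadiocarbonDataset:
    def test_identity_curve_zero_error_returns_calendar_ages(self, identity_curve):
        dates = synthetic.make_radiocarbon_dataset(3000, 2950, 8, identity_curve,
                                                   errors=0.0, seed=4)
        rng = np.random.default_rng(4)
        thetas = rng.uniform(2950, 3000, 8)
        np.testing.assert_allclose([b for b, _ in dates], thetas, atol=1e-9)

    def test_fixed_seed_identical(self, wiggly_curve):
        a = synthetic.make_radiocarbon_dataset(3000, 2950, 8, wiggly_curve, 25.0, seed=9)
        b = synthetic.make_radiocarbon_dataset(3000, 2950, 8, wiggly_curve, 25.0, seed=9)
        assert a == b

    def test_draws_stay_in_phase_and_center_on_midpoint(self, identity_curve):
        n = 1000
        dates = synthetic.make_radiocarbon_dataset(3000, 2950, n, identity_curve,
                                                   errors=0.0, seed=11)
        bp = np.array([b for b, _ in dates])
        assert bp.min() >= 2950 and bp.max() <= 3000
        se = 50 / np.sqrt(12) / np.sqrt(n)
        assert abs(bp.mean() - 2975) < 3 * se

    def test_curve_gap_rejected(self, identity_curve):
        with pytest.raises(ValueError, match="cover"):
            synthetic.make_radiocarbon_dataset(9000, 8950, 4, identity_curve, 20.0)
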