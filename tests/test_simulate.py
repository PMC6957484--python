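"""Synthetic-data generator: beat closed form, coupling, glucose, CGM."""

import dataclasses

import numpy as np
import pytest

from ecglow.simulate import (GlucoseDynamics, MorphParams, NoiseModel,
                             SubjectProfile, WaveParams, cgm_observe,
                             couple_morphology, default_wave_params,
                             simulate_glucose_night, simulate_night,
                             simulate_subject, synth_beat)


class TestSynthBeat:
    def test_zero_amplitudes_give_flat_waveform(self):
        morph = MorphParams(*(WaveParams(0.0, c, 10.0)
                              for c in (-180, -25, 0, 25, 300)))
        _, y = synth_beat(morph)
        assert np.all(y == 0)

    def test_r_peak_is_global_argmax_at_its_center(self):
        morph = default_wave_params()
        t, y = synth_beat(morph, fs=250)
        assert abs(t[np.argmax(y)] - morph.r.center) <= 1000.0 / 250  # within 1 sample

    def test_rt_peak_distance_matches_closed_form(self):
        # T centered 300 ms after R -> 75 samples apart at 250 Hz
        base = default_wave_params()
        morph = dataclasses.replace(base, t=dataclasses.replace(base.t, center=300.0))
        t, y = synth_beat(morph, fs=250)
        r_idx = np.argmin(np.abs(t - 0.0))
        t_lo = np.searchsorted(t, 150.0)
        t_idx = t_lo + np.argmax(y[t_lo:])
        assert t_idx - r_idx == 75

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            WaveParams(1.0, 0.0, 0.0)


class TestCoupling:
    def test_above_onset_returns_baseline(self):
        p = SubjectProfile()
        assert couple_morphology(5.0, p) is p.wave_params

    def test_below_onset_shifts_t_center_by_delta_qt(self):
        p = SubjectProfile()
        m = couple_morphology(3.0, p)
        assert m.t.center == pytest.approx(p.wave_params.t.center + 40.0)

    def test_below_onset_scales_t_and_p_amplitudes(self):
        p = SubjectProfile()
        m = couple_morphology(3.0, p)
        assert m.t.amplitude == pytest.approx(0.7 * p.wave_params.t.amplitude)
        assert m.p.amplitude == pytest.approx(1.3 * p.wave_params.p.amplitude)

    def test_coupling_is_a_step_not_a_ramp(self):
        p = SubjectProfile()
        just_below = couple_morphology(3.999, p)
        deep = couple_morphology(2.5, p)
        assert just_below == deep


class TestGlucoseNight:
    def test_quiet_dynamics_give_constant_baseline(self, clean_profile):
        trace = simulate_glucose_night(clean_profile, seed=1)
        assert np.allclose(trace.values, clean_profile.glucose_dynamics.baseline)

    def test_full_night_grid_covers_midnight_to_nine(self):
        trace = simulate_glucose_night(SubjectProfile(), seed=2)
        assert trace.timestamps.size == 541
        assert trace.timestamps[0] == 0.0
        assert trace.timestamps[-1] == 540 * 60.0

    def test_values_stay_in_physiological_band(self):
        for seed in range(5):
            trace = simulate_glucose_night(SubjectProfile(), seed=seed)
            assert trace.values.min() > 2.0
            assert trace.values.max() <= 12.0

    def test_same_seed_reproduces_trace(self):
        a = simulate_glucose_night(SubjectProfile(), seed=9)
        b = simulate_glucose_night(SubjectProfile(), seed=9)
        assert np.array_equal(a.values, b.values)

    def test_dip_count_follows_poisson_law(self):
        # dip_rate 2/night over 1000 nights: mean within 3 standard errors
        profile = SubjectProfile(
            glucose_dynamics=GlucoseDynamics(dip_rate=2.0))
        counts = [simulate_glucose_night(profile, seed=s).n_dips for s in range(1000)]
        se = np.sqrt(2.0 / 1000)
        assert abs(np.mean(counts) - 2.0) < 3 * se


class TestCGM:
    def test_zero_noise_equals_lagged_truth(self, clean_profile):
        trace = simulate_glucose_night(SubjectProfile(), seed=3)
        cgm = cgm_observe(trace, lag=300, mard_target=0.0, seed=0)
        assert np.allclose(cgm.values, trace.at(cgm.timestamps - 300), atol=1e-12)

    def test_fifteen_minute_grid_gives_37_readings_per_night(self):
        trace = simulate_glucose_night(SubjectProfile(), seed=4)
        cgm = cgm_observe(trace, lag=0.0, mard_target=0.0, interval=900, seed=0)
        assert cgm.timestamps.size == 37

    def test_empirical_mard_matches_target(self):
        # 10^4 readings at target 11.4% -> empirical MARD in [10.4, 12.4]
        rng = np.random.default_rng(0)
        from ecglow.simulate import TrueGlucoseTrace
        t = np.arange(10_001, dtype=float) * 60.0
        trace = TrueGlucoseTrace(timestamps=t, values=np.full(t.size, 5.0))
        cgm = cgm_observe(trace, lag=0.0, mard_target=11.4, interval=60.0, seed=1)
        truth = trace.at(cgm.timestamps)
        mard = 100.0 * np.mean(np.abs(cgm.values - truth) / truth)
        assert 10.4 <= mard <= 12.4

    def test_lag_beyond_coverage_raises(self):
        from ecglow.simulate import TrueGlucoseTrace
        trace = TrueGlucoseTrace(timestamps=np.asarray([0.0, 60.0]),
                                 values=np.asarray([5.0, 5.0]))
        with pytest.raises(ValueError):
            cgm_observe(trace, lag=600.0)


class TestSubjectSimulation:
    def test_deterministic_hr_gives_one_second_intervals(self, clean_night):
        rr = np.diff(clean_night.truth_r_times)
        assert np.allclose(rr, 1.0)

    def test_same_profile_and_seed_bit_identical(self):
        p = SubjectProfile(seed=5)
        a = simulate_subject(p, n_nights=2, seed=5, night_minutes=5)
        b = simulate_subject(p, n_nights=2, seed=5, night_minutes=5)
        for na, nb in zip(a.nights, b.nights):
            assert np.array_equal(na.ecg.samples, nb.ecg.samples)
            assert np.array_equal(na.cgm.values, nb.cgm.values)
            assert np.array_equal(na.accel, nb.accel)

    def test_no_dip_profile_has_no_low_glucose_beats(self, clean_profile):
        rec = simulate_subject(clean_profile, n_nights=2, seed=8, night_minutes=10)
        for night in rec.nights:
            g = night.true_glucose.at(night.truth_r_times)
            assert np.all(g >= 4.0)

    def test_fewer_than_two_nights_rejected(self):
        with pytest.raises(ValueError):
            simulate_subject(SubjectProfile(), n_nights=1)

    def test_rendered_ecg_matches_sum_of_closed_forms(self, clean_profile):
        # spectral sanity: with all noise off the signal is exactly the Gaussian sum
        night = simulate_night(clean_profile, seed=6, night_minutes=6)
        t_s = np.arange(night.ecg.samples.size) / 250.0
        expected = np.zeros_like(t_s)
        for r_t, morph in zip(night.truth_r_times, night.truth_morphs):
            for w in morph.waves().values():
                t_ms = (t_s - r_t) * 1000.0 - w.center
                expected += w.amplitude * np.exp(-(t_ms ** 2) / (2 * w.width ** 2))
        assert np.max(np.abs(night.ecg.samples - expected)) < 1e-9

    def test_truth_morphs_rederivable_from_profile_and_glucose(self, short_recording):
        # coupling faithfulness on a night with real dips
        profile = short_recording.profile
        night = short_recording.nights[0]
        g = night.true_glucose.at(night.truth_r_times)
        for gi, stored in zip(g[:500], night.truth_morphs[:500]):
            assert couple_morphology(gi, profile) == stored


class TestProfileValidation:
    def test_misordered_wave_centers_rejected(self):
        waves = default_wave_params()
        bad = dataclasses.replace(waves, t=dataclasses.replace(waves.t, center=-300.0))
        with pytest.raises(ValueError):
            SubjectProfile(wave_params=bad)

    def test_amplitude_beyond_device_range_rejected(self):
        waves = default_wave_params()
        bad = dataclasses.replace(waves, r=dataclasses.replace(waves.r, amplitude=20.0))
        with pytest.raises(ValueError):
            SubjectProfile(wave_params=bad)
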