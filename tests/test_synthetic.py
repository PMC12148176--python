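import numpy as np
import pytest

from ocutremor import (
    ParticipantProfile,
    SimulationConfig,
    sample_profiles,
    simulate_recording,
    simulate_trials,
)
from ocutremor.kinematics import FIX
from ocutremor.synthetic import detection_probability, simulate_cohort


class TestSampleProfiles:
    def test_degenerate_band_identity_link(self):
        cfg = SimulationConfig(seed=7)
        (p,) = sample_profiles(
            1, cfg, link_params={"slope": 1.0, "intercept": 0.0, "noise_sd": 0.0},
            tremor_band=(150.0, 150.0),
        )
        assert p.tremor_freq == 150.0 and p.cfft == 150.0

    def test_uniform_band_mean(self):
        cfg = SimulationConfig(seed=11)
        profiles = sample_profiles(1000, cfg)
        freqs = np.array([p.tremor_freq for p in profiles])
        se = (150 - 70) / np.sqrt(12) / np.sqrt(1000)
        assert abs(freqs.mean() - 110.0) < 3 * se

    def test_all_draws_within_band(self):
        profiles = sample_profiles(500, SimulationConfig(seed=2))
        assert all(70.0 <= p.tremor_freq <= 150.0 for p in profiles)

    def test_reproducible_with_seed(self):
        cfg = SimulationConfig(seed=5)
        a = sample_profiles(10, cfg)
        b = sample_profiles(10, cfg)
        assert [(p.tremor_freq, p.cfft) for p in a] == [(q.tremor_freq, q.cfft) for q in b]

    def test_invalid_inputs(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            sample_profiles(0, cfg)
        with pytest.raises(ValueError):
            sample_profiles(1, cfg, tremor_band=(150.0, 70.0))


class TestSimulateRecording:
    def test_pure_tremor_is_periodic(self, pure_tremor_recording):
        rec = pure_tremor_recording
        fix = rec.labels == FIX
        # one contiguous fixation span, interior
        runs = np.flatnonzero(np.diff(np.concatenate([[0], fix.view(np.int8), [0]])))
        start, stop = runs[0], runs[1]
        span = slice(start + 5, stop - 5)
        period = round(1000.0 / 150.0 * 3)  # 3 tremor periods = 20 samples
        x = rec.x[span]
        assert np.allclose(x[:-period], x[period:], atol=1e-9)

    def test_motionless_configuration_is_piecewise_constant(self):
        cfg = SimulationConfig(
            duration=3.0, seed=4, noise_sd=0.0, tremor_phase_jitter=0.0,
            microsaccade_rate=0.0,
        )
        prof = ParticipantProfile("P0", tremor_freq=100.0, tremor_amp=1e-12,
                                  drift_diffusion=0.0)
        rec = simulate_recording(prof, cfg)
        fix = rec.labels == FIX
        dx = np.abs(np.diff(rec.x))
        both_fix = fix[:-1] & fix[1:]
        assert np.max(dx[both_fix]) < 1e-9

    def test_fix_fraction_above_half(self, tremor_recording):
        assert np.mean(tremor_recording.labels == FIX) > 0.5

    def test_labels_partition_samples(self, tremor_recording):
        assert set(np.unique(tremor_recording.labels)) <= {"FIX", "SACC", "BLINK"}
        assert len(tremor_recording.labels) == len(tremor_recording)

    def test_tremor_peak_in_fix_velocity_spectrum(self):
        cfg = SimulationConfig(duration=10.0, seed=9, tremor_phase_jitter=0.0)
        prof = ParticipantProfile("P0", tremor_freq=150.0)
        rec = simulate_recording(prof, cfg)
        fix = rec.labels == FIX
        runs = np.flatnonzero(np.diff(np.concatenate([[0], fix.view(np.int8), [0]])))
        start, stop = runs[0], runs[1]
        vx = np.diff(rec.x[start:stop])
        vx = vx - vx.mean()
        freqs = np.fft.rfftfreq(len(vx), d=1e-3)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(vx)) ** 2)]
        assert abs(peak - 150.0) <= freqs[1] - freqs[0]

    def test_alternates_between_two_targets(self, tremor_recording):
        fix_x = tremor_recording.x[tremor_recording.labels == FIX]
        near_left = np.mean(np.abs(fix_x + 9.5) < 1.5)
        near_right = np.mean(np.abs(fix_x - 9.5) < 1.5)
        assert near_left > 0.2 and near_right > 0.2

    def test_drift_variance_grows_linearly(self):
        # pure drift: displacement variance over lag t must scale like t
        cfg = SimulationConfig(
            duration=30.0, seed=21, noise_sd=0.0, tremor_phase_jitter=0.0,
            microsaccade_rate=0.0, fixation_mean_duration=3000.0,
        )
        prof = ParticipantProfile("P0", tremor_freq=100.0, tremor_amp=1e-12,
                                  drift_diffusion=0.02)
        rec = simulate_recording(prof, cfg)
        fix = rec.labels == FIX
        # restrict pairs to the same fixation: drift resets at saccades
        seg_id = np.cumsum(np.concatenate([[0], (np.diff(fix.view(np.int8)) != 0)]))
        x = np.where(fix, rec.x, np.nan)
        var = {}
        for lag in (50, 100, 200):
            same = seg_id[lag:] == seg_id[:-lag]
            d = (x[lag:] - x[:-lag])[same]
            var[lag] = np.nanvar(d)
        assert var[100] / var[50] == pytest.approx(2.0, rel=0.35)
        assert var[200] / var[100] == pytest.approx(2.0, rel=0.35)

    def test_blinks_carry_missing_positions(self):
        cfg = SimulationConfig(duration=10.0, seed=3, blink_rate=0.5)
        prof = ParticipantProfile("P0", tremor_freq=100.0)
        rec = simulate_recording(prof, cfg)
        blink = rec.labels == "BLINK"
        assert blink.any()
        assert np.all(np.isnan(rec.x[blink]))
        assert np.all(np.isfinite(rec.x[~blink]))

    def test_bit_reproducible(self, tremor_profile):
        cfg = SimulationConfig(duration=5.0, seed=42)
        a = simulate_recording(tremor_profile, cfg)
        b = simulate_recording(tremor_profile, cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.labels, b.labels)

    def test_duration_shorter_than_fixation_rejected(self, tremor_profile):
        cfg = SimulationConfig(duration=0.2, seed=0, fixation_mean_duration=600.0)
        with pytest.raises(ValueError):
            simulate_recording(tremor_profile, cfg)

    def test_sampling_interval_must_divide_duration(self, tremor_profile):
        cfg = SimulationConfig(duration=1.0005, sampling_interval=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_recording(tremor_profile, cfg)


class TestSimulateTrials:
    def test_saturated_detection_all_correct(self):
        prof = ParticipantProfile("P0", tremor_freq=150.0, cfft=10_000.0,
                                  detection_slope=1.0)
        trials = simulate_trials(prof, SimulationConfig(seed=0))
        assert len(trials) == 9
        assert all(t.correct for t in trials)

    def test_nine_trials_three_per_frequency(self):
        prof = ParticipantProfile("P0", tremor_freq=100.0)
        trials = simulate_trials(prof, SimulationConfig(seed=1))
        freqs = sorted({t.flicker_freq for t in trials})
        assert freqs == [30.0, 60.0, 120.0]
        assert all(sum(t.flicker_freq == f for t in trials) == 3 for f in freqs)

    def test_flat_slope_gives_two_thirds_correct(self):
        # slope 0: p_correct = 1/3 + (2/3)(1/2) = 2/3 regardless of cfft
        assert detection_probability(
            ParticipantProfile("P0", tremor_freq=100.0, detection_slope=0.0), 60.0
        ) == pytest.approx(2 / 3)
        prof = ParticipantProfile("P0", tremor_freq=100.0, detection_slope=0.0)
        rng = np.random.default_rng(8)
        cfg = SimulationConfig(seed=0, trials_per_frequency=400)
        trials = simulate_trials(prof, cfg, rng=rng)
        frac = np.mean([t.correct for t in trials])
        se = np.sqrt((2 / 3) * (1 / 3) / len(trials))
        assert abs(frac - 2 / 3) < 3 * se

    def test_reproducible_with_seed(self):
        prof = ParticipantProfile("P0", tremor_freq=100.0)
        cfg = SimulationConfig(seed=13)
        a = simulate_trials(prof, cfg)
        b = simulate_trials(prof, cfg)
        assert [(t.true_side, t.answer) for t in a] == [(t.true_side, t.answer) for t in b]


class TestCohort:
    def test_cohort_shapes_and_reproducibility(self):
        cfg = SimulationConfig(duration=2.0, seed=6, fixation_mean_duration=300.0)
        profiles, recs, trials = simulate_cohort(3, cfg)
        assert len(profiles) == len(recs) == 3
        assert len(trials) == 27
        _, recs2, trials2 = simulate_cohort(3, cfg)
        assert np.array_equal(recs[1].x, recs2[1].x)
        assert [(t.participant_id, t.answer) for t in trials] == [
            (t.participant_id, t.answer) for t in trials2
        ]
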