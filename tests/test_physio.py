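"""Waveform preprocessing: beats, IBI cleaning, HR/RV/PETCO2 timecourses, HRV metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import boldphysio as bp
from boldphysio.physio import rmssd_ms

from conftest import pulse_train


def beats_from_ibis(ibis, t0=0.0):
    times = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    return bp.BeatSeries(beat_times_s=times)


class TestDetectBeats:
    def test_periodic_train_yields_unit_ibis(self):
        rec = pulse_train(1.0, 60.0, fs=50.0)
        beats = bp.detect_beats(rec)
        assert abs(len(beats.beat_times_s) - 60) <= 1
        assert np.allclose(beats.ibi_s, 1.0, atol=0.05)

    def test_moderate_noise_preserves_beat_count(self):
        rec = pulse_train(1.0, 60.0, fs=50.0)
        clean_count = len(bp.detect_beats(rec).beat_times_s)
        rng = np.random.default_rng(0)
        sigma = np.sqrt(np.mean(rec.samples**2)) / 10.0  # SNR 20 dB
        noisy = bp.PhysioRecording(rec.samples + sigma * rng.standard_normal(len(rec.samples)), rec.fs, "ppg")
        assert len(bp.detect_beats(noisy).beat_times_s) == clean_count

    def test_flat_signal_raises(self):
        rec = bp.PhysioRecording(np.zeros(3000), 50.0, "ppg")
        with pytest.raises(bp.DataError, match="no cardiac rhythm"):
            bp.detect_beats(rec)

    def test_wrong_modality_rejected(self):
        rec = bp.PhysioRecording(np.sin(np.arange(3000) / 10), 50.0, "respiration")
        with pytest.raises(bp.DataError):
            bp.detect_beats(rec)


class TestCleanIBI:
    def test_clean_data_passes_through(self):
        # smooth physiological modulation, no artifacts
        ibis = 0.8 + 0.02 * np.sin(2 * np.pi * 0.1 * np.arange(50) * 0.8)
        beats = beats_from_ibis(ibis)
        out = bp.clean_ibi(beats)
        assert np.allclose(out.beat_times_s, beats.beat_times_s)
        assert not out.artifact_mask.any()

    def test_single_spike_interpolated_from_neighbors(self):
        ibis = np.array([0.8] * 5 + [4.0] + [0.8] * 5)
        out = bp.clean_ibi(beats_from_ibis(ibis))
        assert out.artifact_mask[5]
        assert out.ibi_s[5] == pytest.approx(0.8)

    def test_adjacent_spikes_interpolated_from_flanking_pair(self):
        ibis = np.array([0.8, 0.8, 4.0, 4.0, 0.8, 0.8])
        out = bp.clean_ibi(beats_from_ibis(ibis))
        # linear interpolation between the flanking valid intervals (both 0.8)
        assert np.allclose(out.ibi_s, 0.8)

    def test_majority_flagged_sets_quality_warning(self):
        ibis = np.array([0.8, 0.8] + [3.0, 0.1] * 4)
        with pytest.warns(UserWarning, match="50%"):
            out = bp.clean_ibi(beats_from_ibis(ibis))
        assert out.quality_warning


class TestHRTimecourse:
    @pytest.mark.parametrize("ibi, hr", [(1.0, 60.0), (0.75, 80.0)])
    def test_constant_ibi_gives_constant_hr(self, ibi, hr):
        beats = beats_from_ibis(np.full(200, ibi))
        tc = bp.hr_timecourse(beats, tr_s=1.4, n_vols=60)
        assert np.allclose(tc.values, hr)

    def test_alternating_ibis_match_windowed_median_oracle(self):
        ibis = np.tile([0.8, 1.0], 60)
        beats = beats_from_ibis(ibis)
        tr, n_vols = 1.4, 50
        tc = bp.hr_timecourse(beats, tr, n_vols)
        mids = beats.ibi_midpoints_s
        for i in range(n_vols):  # brute-force window contents
            t = i * tr
            sel = (mids >= t - 3.0) & (mids <= t + 3.0)
            assert tc.values[i] == pytest.approx(60.0 / np.median(beats.ibi_s[sel]))


class TestHRVMetrics:
    def test_rmssd_worked_example(self):
        assert rmssd_ms([800, 850, 790, 820]) == pytest.approx(
            np.sqrt((50**2 + 60**2 + 30**2) / 3)
        )
        assert rmssd_ms([800, 850, 790, 820]) == pytest.approx(48.3, abs=0.1)

    def test_constant_ibi_has_no_variability(self, quiet):
        beats = beats_from_ibis(np.full(300, 0.9))
        m = bp.hrv_metrics(beats)
        # RMSSD and band powers vanish (up to float noise in the beat times)
        assert np.isnan(m.ln_rmssd) or np.exp(m.ln_rmssd) < 1e-9
        assert np.isnan(m.ln_lf) or np.exp(m.ln_lf) < 1e-12
        assert np.isnan(m.ln_hf) or np.exp(m.ln_hf) < 1e-12
        assert m.avg_hr_bpm == pytest.approx(60 / 0.9)

    def test_slow_sinusoidal_ibi_concentrates_power_in_lf(self):
        t, ibis = 0.0, []
        while t < 360.0:
            ibi = 1.0 + 0.05 * np.sin(2 * np.pi * 0.1 * t)
            ibis.append(ibi)
            t += ibi
        beats = beats_from_ibis(np.array(ibis))
        m = bp.hrv_metrics(beats)
        lf, hf = np.exp(m.ln_lf), np.exp(m.ln_hf)
        assert lf / (lf + hf) >= 0.90

    def test_metrics_invariant_to_time_offset(self):
        rng = np.random.default_rng(2)
        ibis = 0.9 + 0.05 * rng.standard_normal(300)
        a = bp.hrv_metrics(beats_from_ibis(ibis, t0=0.0))
        b = bp.hrv_metrics(beats_from_ibis(ibis, t0=57.3))
        assert a.ln_rmssd == pytest.approx(b.ln_rmssd)
        assert a.ln_lf == pytest.approx(b.ln_lf)
        assert a.ln_hf == pytest.approx(b.ln_hf)

    def test_short_recording_rejected(self):
        with pytest.raises(bp.DataError):
            bp.hrv_metrics(beats_from_ibis(np.full(30, 0.9)))


class TestRVTimecourse:
    def test_unit_sinusoid_gives_inverse_sqrt2(self):
        fs = 25.0
        t = np.arange(int(120 * fs)) / fs
        rec = bp.PhysioRecording(np.sin(2 * np.pi * 0.25 * t + 0.7), fs, "respiration")
        tc = bp.rv_timecourse(rec, tr_s=2.0, n_vols=50)
        assert np.allclose(tc.values[5:45], 1 / np.sqrt(2), atol=0.02)

    def test_constant_waveform_gives_zero_rv(self):
        rec = bp.PhysioRecording(np.full(3000, 2.5), 25.0, "respiration")
        with pytest.warns(UserWarning, match="constant"):
            tc = bp.rv_timecourse(rec, tr_s=2.0, n_vols=50)
        assert np.all(tc.values == 0)

    def test_amplitude_step_doubles_rv(self):
        fs = 25.0
        t = np.arange(int(200 * fs)) / fs
        amp = np.where(t < 100, 1.0, 2.0)
        rec = bp.PhysioRecording(amp * np.sin(2 * np.pi * 0.25 * t), fs, "respiration")
        tc = bp.rv_timecourse(rec, tr_s=2.0, n_vols=100)
        early, late = tc.values[10:40].mean(), tc.values[60:90].mean()
        assert late / early == pytest.approx(2.0, rel=0.02)

    def test_matches_windowed_sd_oracle(self):
        rng = np.random.default_rng(3)
        fs, tr, n_vols = 20.0, 1.4, 40
        samples = rng.standard_normal(int(80 * fs))
        rec = bp.PhysioRecording(samples, fs, "respiration")
        tc = bp.rv_timecourse(rec, tr, n_vols)
        t = np.arange(len(samples)) / fs
        for i in range(n_vols):
            sel = (t >= i * tr - 3.0) & (t <= i * tr + 3.0)
            assert tc.values[i] == pytest.approx(samples[sel].std())


class TestNormalizeRV:
    def test_symmetric_case(self):
        tc = bp.PhysioTimecourse([-2.0, -1.0, 0.0, 1.0, 2.0], 1.0, "rv_norm")
        out = bp.normalize_rv(tc, pct=(0.0, 100.0))
        assert np.allclose(out.values, [-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_matches_three_step_oracle_on_seeded_sample(self):
        rng = np.random.default_rng(7)
        v = rng.gamma(2.0, 1.5, size=404)  # skewed, like real RV
        out = bp.normalize_rv(bp.PhysioTimecourse(v, 1.4, "rv_norm"))
        # independent re-implementation of the three steps
        lo, hi = np.percentile(v, [1.45, 98.55])
        m = v[(v >= lo) & (v <= hi)].mean()
        oracle = np.array([(x - m) / (hi - m) if x >= m else (x - m) / abs(lo - m) for x in v])
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_in_bounds_outputs_lie_in_unit_interval(self):
        rng = np.random.default_rng(8)
        v = rng.lognormal(size=500)
        lo, hi = np.percentile(v, [1.45, 98.55])
        out = bp.normalize_rv(bp.PhysioTimecourse(v, 1.0, "rv_norm"))
        inb = (v >= lo) & (v <= hi)
        assert out.values[inb].min() >= -1.0 - 1e-12
        assert out.values[inb].max() <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=0.01, max_value=100.0), seed=st.integers(0, 50))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        v = rng.gamma(2.0, 1.0, size=100) + 0.1
        a = bp.normalize_rv(bp.PhysioTimecourse(v, 1.0, "rv_norm")).values
        b = bp.normalize_rv(bp.PhysioTimecourse(scale * v, 1.0, "rv_norm")).values
        assert np.allclose(a, b, atol=1e-9)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(bp.DataError, match="degenerate"):
            bp.normalize_rv(bp.PhysioTimecourse(np.ones(100), 1.0, "rv_norm"))


class TestBreathingRate:
    @pytest.mark.parametrize("freq, dur, bpm", [(0.25, 120.0, 15.0), (0.30, 120.0, 18.0)])
    def test_sinusoid_rates(self, freq, dur, bpm):
        fs = 25.0
        t = np.arange(int(dur * fs)) / fs
        rec = bp.PhysioRecording(np.sin(2 * np.pi * freq * t), fs, "respiration")
        assert bp.breathing_rate(rec) == pytest.approx(bpm, abs=0.5)

    def test_jittered_breathing_matches_peak_count_oracle(self):
        rng = np.random.default_rng(5)
        fs, pieces, t0 = 25.0, [], 0.0
        periods = 4.0 + 0.5 * rng.standard_normal(40)
        for p in np.clip(periods, 2.5, 6.0):
            n = int(round(p * fs))
            pieces.append(np.sin(2 * np.pi * np.arange(n) / n))
            t0 += p
        samples = np.concatenate(pieces)
        rec = bp.PhysioRecording(samples, fs, "respiration")
        n_cycles = len(periods)
        expected = n_cycles / rec.duration_s * 60.0
        assert bp.breathing_rate(rec) == pytest.approx(expected, rel=0.06)

    def test_too_short_rejected(self):
        rec = bp.PhysioRecording(np.sin(np.arange(200) / 5), 25.0, "respiration")
        with pytest.raises(bp.DataError):
            bp.breathing_rate(rec)


class TestCapnograph:
    @staticmethod
    def _pair(delay_s, fs=10.0, dur=300.0):
        t = np.arange(int(dur * fs)) / fs
        # two incommensurate tones: aperiodic, so the optimum shift is unique
        resp = np.sin(2 * np.pi * 0.25 * t) + 0.4 * np.sin(2 * np.pi * 0.11 * np.sqrt(2) * t + 1.0)
        k = int(round(delay_s * fs))
        co2 = -np.concatenate([resp[:1].repeat(k), resp[: len(resp) - k]])
        return (
            bp.PhysioRecording(co2, fs, "capnograph"),
            bp.PhysioRecording(resp, fs, "respiration"),
        )

    @pytest.mark.parametrize("delay", [0.0, 3.0])
    def test_constructed_inverse_delay_recovered(self, delay):
        co2, resp = self._pair(delay)
        assert bp.align_capnograph(co2, resp, max_shift_s=6.0) == pytest.approx(delay)

    def test_fractional_delay_recovered_within_one_sample(self):
        fs = 10.0
        t = np.arange(int(300 * fs)) / fs
        resp = np.sin(2 * np.pi * 0.25 * t)
        co2 = -np.sin(2 * np.pi * 0.25 * (t - 1.7))
        shift = bp.align_capnograph(
            bp.PhysioRecording(co2, fs, "capnograph"),
            bp.PhysioRecording(resp, fs, "respiration"),
            max_shift_s=1.9,  # within a quarter-period so the optimum is unique
        )
        assert abs(shift - 1.7) <= 0.1 + 1e-9

    def test_square_wave_plateaus_give_constant_petco2(self):
        fs, dur = 25.0, 120.0
        t = np.arange(int(dur * fs)) / fs
        co2 = np.where(np.sin(2 * np.pi * 0.25 * t) > 0, 40.0, 0.0)
        rec = bp.PhysioRecording(co2, fs, "capnograph")
        tc = bp.petco2_timecourse(rec, 0.0, tr_s=2.4, n_vols=40)
        assert np.allclose(tc.values, 40.0)

    def test_ramping_plateaus_give_monotone_series(self):
        fs, dur = 25.0, 240.0
        t = np.arange(int(dur * fs)) / fs
        plateau = 38.0 + 4.0 * t / dur
        co2 = np.where(np.sin(2 * np.pi * 0.25 * t) > 0, plateau, 0.0)
        rec = bp.PhysioRecording(co2, fs, "capnograph")
        tc = bp.petco2_timecourse(rec, 0.0, tr_s=2.4, n_vols=90)
        d = np.diff(tc.values[2:-2])
        assert np.all(d >= -1e-9) and tc.values[-1] > tc.values[0] + 2.0

    def test_single_breath_rejected(self):
        fs = 25.0
        t = np.arange(int(4 * fs)) / fs
        co2 = np.where(np.sin(2 * np.pi * 0.25 * t) > 0, 40.0, 0.0)
        with pytest.raises(bp.DataError):
            bp.petco2_timecourse(bp.PhysioRecording(co2, fs, "capnograph"), 0.0, 2.4, 10)


class TestIQRScreen:
    def test_outlier_excluded(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])
        mask = bp.iqr_screen(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        oracle = (vals >= q1 - 1.5 * (q3 - q1)) & (vals <= q3 + 1.5 * (q3 - q1))
        assert np.array_equal(mask, oracle)
        assert not mask[-1] and mask[:-1].all()

    def test_identical_values_all_retained(self):
        assert bp.iqr_screen(np.full(10, 3.3)).all()

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 100))
    def test_symmetric_clean_samples_fully_retained(self, seed):
        v = np.random.default_rng(seed).uniform(-1, 1, size=50)
        assert bp.iqr_screen(v).sum() >= 48  # uniform has no 1.5-IQR outliers


class TestScenarioRecovery:
    def test_preprocessing_recovers_generator_parameters(self, scenario404, quiet):
        recs = bp.simulate_physio(scenario404, "young01")
        beats = bp.clean_ibi(bp.detect_beats(recs["ppg"]))
        gp = scenario404.group_params["young"]
        hr = bp.hr_timecourse(beats, scenario404.tr_s, scenario404.n_vols)
        assert np.mean(hr.values) == pytest.approx(gp.mean_hr_bpm, rel=0.01)
        assert bp.breathing_rate(recs["respiration"]) == pytest.approx(
            gp.breathing_rate_bpm, abs=0.5
        )
        assert np.isfinite(hr.values).all() and len(hr.values) == scenario404.n_vols
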