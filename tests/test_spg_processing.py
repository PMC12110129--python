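"""SPG chain: filtering, baseline removal, normalization, peak detection, APG."""

import numpy as np
import pytest

from conftest import TEST_FS_HZ, matched_errors_ms
from strainpulse.errors import ConfigurationError, DomainError
from strainpulse.pipeline import process_spg
from strainpulse.spg_processing import (FilterSpec, bandpass, derive_apg,
                                        detect_apg_peaks, detect_onsets,
                                        detect_systolic_peaks, normalize,
                                        remove_baseline)
from strainpulse.synthetic_data import RecordingConfig, make_recording
from strainpulse.traces import SignalTrace


def _sine(freq_hz, fs=TEST_FS_HZ, duration=10.0, amp=1.0, offset=0.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalTrace(offset + amp * np.sin(2 * np.pi * freq_hz * t), fs, "ue")


class TestBandpass:
    def test_in_band_sinusoid_amplitude_and_peak_time_preserved(self):
        out = bandpass(_sine(2.0))
        mid = out.values[2000:8000]
        assert 0.95 <= mid.max() <= 1.05
        # peak of the input at t = 0.125 s within each cycle
        i = 2000 + np.argmax(mid[:500])
        in_peak = 2000 + np.argmax(_sine(2.0).values[2000:2500])
        assert abs(i - in_peak) <= 1

    def test_dc_offset_removed(self):
        out = bandpass(_sine(2.0, offset=5.0))
        assert abs(np.mean(out.values[1000:-1000])) < 5e-3

    def test_out_of_band_sinusoid_attenuated(self):
        out = bandpass(_sine(50.0))
        assert np.max(np.abs(out.values[2000:8000])) <= 0.2

    def test_band_edge_above_nyquist_raises(self):
        with pytest.raises(ConfigurationError):
            bandpass(_sine(2.0, fs=40.0), FilterSpec(low_hz=0.5, high_hz=25.0))


class TestOnsets:
    def test_noiseless_recording_onsets_match_ground_truth(
            self, noiseless_recording, noiseless_analysis):
        truth = noiseless_recording.ground_truth.spg["onset"]
        det = noiseless_analysis.spg.onset_times_s
        err, n_true = matched_errors_ms(det, truth, window_s=0.1)
        # interior beats are all recovered; the first onset may be lost to the
        # filter's start-up edge
        assert err.size >= n_true - 1
        assert np.max(np.abs(err)) <= 10.0

    def test_constant_trace_has_no_onsets(self):
        trace = SignalTrace(np.ones(5000), TEST_FS_HZ, "ue")
        assert detect_onsets(trace).size == 0


class TestBaselineRemoval:
    def test_output_is_zero_at_onset_samples(self, noiseless_analysis):
        filt = noiseless_analysis.spg  # normalized output of the chain
        trace = SignalTrace(np.sin(np.arange(5000) / 100.0) + 0.3, TEST_FS_HZ)
        onsets = np.array([500, 1500, 2500, 4000])
        out = remove_baseline(trace, onsets)
        assert np.allclose(out.values[onsets], 0.0)

    def test_linear_ramp_is_its_own_baseline(self):
        ramp = SignalTrace(np.linspace(0, 5, 3000), TEST_FS_HZ)
        out = remove_baseline(ramp, np.array([0, 2999]))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_idempotent_for_fixed_onsets(self):
        trace = SignalTrace(np.random.default_rng(0).normal(size=3000), TEST_FS_HZ)
        onsets = np.array([100, 900, 1700, 2500])
        once = remove_baseline(trace, onsets)
        twice = remove_baseline(once, onsets)
        assert np.allclose(once.values, twice.values)

    def test_respiratory_drift_suppressed_at_onset_anchors(self):
        cfg_drift = RecordingConfig(duration_s=20.0, fs_hz=TEST_FS_HZ, noise_rms_aF=0.0,
                                    scg_noise_rms=0.0, adc_bits=20,
                                    drift_mode="respiratory", drift_amplitude_ue=20.0)
        rec = make_recording(cfg_drift, rng_seed=2)
        filtered = bandpass(rec.spg_counts)
        onsets = detect_onsets(filtered)
        assert onsets.size >= 2
        pre_rms = np.sqrt(np.mean(filtered.values[onsets] ** 2))
        post = remove_baseline(filtered, onsets)
        post_rms = np.sqrt(np.mean(post.values[onsets] ** 2))
        assert post_rms <= 0.1 * pre_rms

    def test_fewer_than_two_onsets_raises(self):
        with pytest.raises(DomainError):
            remove_baseline(SignalTrace(np.ones(100), TEST_FS_HZ), np.array([5]))


class TestNormalize:
    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        a = normalize(SignalTrace(x, TEST_FS_HZ)).values
        b = normalize(SignalTrace(3.7 * x - 11.0, TEST_FS_HZ)).values
        assert np.allclose(a, b)

    def test_constant_maps_to_zeros_and_range_arithmetic(self):
        assert np.all(normalize(SignalTrace(np.full(10, 4.2), TEST_FS_HZ)).values == 0)
        out = normalize(SignalTrace(np.array([-2.0, 0.0, 6.0]), TEST_FS_HZ)).values
        assert out[1] == pytest.approx(0.25)


class TestSystolicDetection:
    def test_noiseless_recording_systolic_within_five_ms(
            self, noiseless_recording, noiseless_analysis):
        err, n_true = matched_errors_ms(
            noiseless_analysis.spg.systolic_times_s,
            noiseless_recording.ground_truth.spg["systolic"])
        assert err.size == n_true
        assert np.max(np.abs(err)) <= 5.0

    def test_empty_trace_yields_empty_result(self):
        assert detect_systolic_peaks(SignalTrace(np.empty(0), TEST_FS_HZ)).size == 0


class TestApg:
    def test_ramp_derivative_is_constant_slope(self):
        k = 3.5
        ramp = SignalTrace(k * np.arange(2000) / TEST_FS_HZ, TEST_FS_HZ)
        apg = derive_apg(ramp)
        assert np.allclose(apg.values[10:-10], k, rtol=1e-6)

    def test_sinusoid_derivative_amplitude(self):
        apg = derive_apg(_sine(2.0))
        assert np.max(apg.values[1000:-1000]) == pytest.approx(2 * np.pi * 2, rel=0.02)

    def test_apg_peak_precedes_systolic_peak_within_each_beat(self, noiseless_analysis):
        sa = noiseless_analysis.spg
        for sys_t in sa.systolic_times_s:
            before = sa.apg_peak_times_s[(sa.apg_peak_times_s < sys_t)
                                         & (sa.apg_peak_times_s > sys_t - 0.3)]
            assert before.size == 1

    def test_noiseless_apg_peaks_match_max_slope_fiducials(
            self, noiseless_recording, noiseless_analysis):
        err, n_true = matched_errors_ms(
            noiseless_analysis.spg.apg_peak_times_s,
            noiseless_recording.ground_truth.spg["max_slope"])
        assert err.size >= n_true - 1
        assert np.max(np.abs(err)) <= 10.0

    def test_constant_apg_has_no_peaks(self):
        assert detect_apg_peaks(SignalTrace(np.zeros(1000), TEST_FS_HZ)).size == 0

    def test_apg_detection_robust_to_grip_artifacts(self):
        cfg = RecordingConfig(duration_s=30.0, fs_hz=TEST_FS_HZ,
                              drift_mode="grip", drift_amplitude_ue=60.0)
        rec = make_recording(cfg, rng_seed=6)
        ana = process_spg(rec.spg_counts)
        n_beats = rec.ground_truth.beat_times_s.size
        # the max-slope point survives pressure artifacts: one APG peak per
        # beat (lead beats may add one)
        assert abs(int(ana.apg_peak_idx.size) - n_beats) <= 1


class TestChainProperties:
    def test_fiducial_indices_invariant_to_input_scaling(self, default_recording):
        trace = default_recording.spg_counts
        a = process_spg(trace)
        b = process_spg(trace.with_values(3.0 * trace.values))
        assert np.array_equal(a.systolic_idx, b.systolic_idx)
        assert np.array_equal(a.onset_idx, b.onset_idx)
        assert np.array_equal(a.apg_peak_idx, b.apg_peak_idx)

    def test_noiseless_beat_recall_and_precision_over_seed_matrix(self):
        cfg = RecordingConfig(duration_s=20.0, fs_hz=TEST_FS_HZ, noise_rms_aF=0.0,
                              scg_noise_rms=0.0, drift_mode=None, adc_bits=20)
        n_true_total = n_matched = n_det_total = 0
        for seed in range(20):
            rec = make_recording(cfg, rng_seed=seed)
            ana = process_spg(rec.spg_counts)
            truth = rec.ground_truth.spg["systolic"]
            err, n_true = matched_errors_ms(ana.systolic_times_s, truth)
            n_true_total += n_true
            n_matched += err.size
            # detected peaks beyond truth+lead beats count against precision
            n_det_total += max(ana.systolic_idx.size - 1, err.size)
        assert n_matched / n_true_total >= 0.99   # recall
        assert n_matched / n_det_total >= 0.99    # precision (lead beat excused)
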