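"""Shared fixtures: seeded synthetic recordings at the 1 kHz test rate."""

from __future__ import annotations

import numpy as np
import pytest

from strainpulse.cardio_metrics import match_beats
from strainpulse.pipeline import analyze_recording
from strainpulse.synthetic_data import RecordingConfig, make_recording

TEST_FS_HZ = 1000.0


@pytest.fixture(scope="session")
def noiseless_recording():
    """30 s recording with noise, drift and coarse quantization disabled."""
    cfg = RecordingConfig(duration_s=30.0, fs_hz=TEST_FS_HZ, noise_rms_aF=0.0,
                          scg_noise_rms=0.0, drift_mode=None, adc_bits=20)
    return make_recording(cfg, rng_seed=3)


@pytest.fixture(scope="session")
def default_recording():
    """30 s recording at the default noise, drift and 14-bit quantization."""
    cfg = RecordingConfig(duration_s=30.0, fs_hz=TEST_FS_HZ)
    return make_recording(cfg, rng_seed=7)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_recording):
    return analyze_recording(noiseless_recording.spg_counts,
                             noiseless_recording.scg_counts)


@pytest.fixture(scope="session")
def default_analysis(default_recording):
    return analyze_recording(default_recording.spg_counts,
                             default_recording.scg_counts)


def matched_errors_ms(detected_s: np.ndarray, true_s: np.ndarray,
                      window_s: float | None = None) -> tuple[np.ndarray, int]:
    """Pair detected and true fiducial times; return errors (ms) and truth count."""
    true_s = np.asarray(true_s, dtype=float)
    true_s = true_s[~np.isnan(true_s)]
    pairs = match_beats(np.asarray(detected_s, dtype=float), true_s, window_s)
    err = np.array([detected_s[i] - true_s[j] for i, j in pairs]) * 1000.0
    return err, true_s.size
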