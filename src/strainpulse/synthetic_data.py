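"""Synthetic paired SPG/SCG recordings with exact ground truth.

Real strain-plethysmography recordings are not required anywhere in the
package: this module generates synchronized two-channel recordings that
emulate the measurement conditions — an SPG channel with the canonical
arterial-pulse morphology (onset, max-slope point, systolic peak, dicrotic
notch, diastolic peak and a second-systolic shoulder), and an SCG channel
whose S1 complex contains the mitral-closure (MC), isovolumic-moment (IM) and
aortic-opening (AO) peaks, with MC and AO deliberately similar in amplitude so
that the two-pass disambiguation problem is actually posed.

Every generated recording carries a :class:`GroundTruth` with the true beat
times, per-beat fiducial times, inter-beat intervals, PAT/PTT and RMSSD,
captured from the noiseless template before sensor noise, drift or
quantization are applied.

Waveform model
--------------
SPG pulses are sums of Gaussian lobes (systolic, second-systolic, diastolic)
with a narrow negative Gaussian forming the dicrotic notch; lobes are smooth
and differentiable so fiducials are well-defined extrema.  SCG components are
Gabor-like wavelets (Gaussian-windowed cosine) whose peak lies exactly at the
component center.  Fiducial times are located numerically on a grid
oversampled ``oversample``× relative to the output sampling rate.

One template beat is prepended and appended around the scored beat plan
(excluded from ground truth) so that edge beats have a well-defined onset
trough and complete SCG segments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .cardio_metrics import rmssd as _rmssd
from .errors import ConfigurationError
from .sensor_model import SensorParams, transduce
from .traces import SignalTrace, write_trace

__all__ = [
    "BeatPlan",
    "PulseShape",
    "ScgShape",
    "GroundTruth",
    "RecordingConfig",
    "SyntheticRecording",
    "generate_beat_times",
    "synth_spg",
    "synth_scg",
    "add_baseline_drift",
    "make_recording",
    "write_recording",
    "default_scg_channel_params",
]

IBI_BOUNDS_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class BeatPlan:
    """Scored beat schedule: strictly increasing beat times and their intervals."""

    beat_times_s: np.ndarray
    ibis_ms: np.ndarray
    target_hr_bpm: float
    target_rmssd_ms: float

    @property
    def n_beats(self) -> int:
        return self.beat_times_s.size

    @property
    def mean_ibi_s(self) -> float:
        return 60.0 / self.target_hr_bpm

    def realized_rmssd_ms(self) -> float:
        return _rmssd(self.ibis_ms)


@dataclass(frozen=True)
class PulseShape:
    """Gaussian-lobe parametrization of one SPG pulse.

    Amplitudes are relative to the systolic lobe; delays are seconds after the
    nominal beat (onset) time.  Defaults reproduce a fingertip-like arterial
    pulse: sharp systolic upstroke, second-systolic shoulder from wave
    reflection, dicrotic notch, low broad diastolic wave.
    """

    systolic_amp: float = 1.0
    systolic_delay_s: float = 0.13
    systolic_width_s: float = 0.05
    second_systolic_amp: float = 0.40
    second_systolic_delay_s: float = 0.23
    second_systolic_width_s: float = 0.07
    notch_depth: float = 0.10
    notch_delay_s: float = 0.30
    notch_width_s: float = 0.025
    diastolic_amp: float = 0.30
    diastolic_delay_s: float = 0.36
    diastolic_width_s: float = 0.08
    runoff_amp: float = 0.15
    runoff_delay_s: float = 0.50
    runoff_width_s: float = 0.22

    def __post_init__(self) -> None:
        for name in ("systolic_amp", "second_systolic_amp", "notch_depth", "diastolic_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def min_width_s(self) -> float:
        return min(self.systolic_width_s, self.second_systolic_width_s,
                   self.notch_width_s, self.diastolic_width_s)

    def components(self) -> list[tuple[float, float, float]]:
        """(amplitude, delay, width) triples; the notch has negative amplitude.

        The broad low-amplitude runoff lobe models the slow diastolic decay of
        arterial pressure, so the trough before each upstroke (the pulse
        onset) is a genuine local minimum rather than a flat segment.
        """
        return [
            (self.systolic_amp, self.systolic_delay_s, self.systolic_width_s),
            (self.second_systolic_amp, self.second_systolic_delay_s,
             self.second_systolic_width_s),
            (-self.notch_depth, self.notch_delay_s, self.notch_width_s),
            (self.diastolic_amp, self.diastolic_delay_s, self.diastolic_width_s),
            (self.runoff_amp, self.runoff_delay_s, self.runoff_width_s),
        ]


@dataclass(frozen=True)
class ScgShape:
    """S1-complex parametrization: MC, IM and AO as Gabor wavelets.

    MC and AO amplitudes must agree within 20% so that amplitude alone cannot
    separate them — the condition that motivates IM-anchored segmentation.
    The IM component is the tallest (positive polarity) so a high-threshold
    first pass isolates it.  ``im_fraction`` places IM between MC and AO.
    """

    mc_amp: float = 0.60
    im_amp: float = 1.0
    ao_amp: float = 0.55
    component_width_s: float = 0.008
    carrier_hz: float = 25.0
    im_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.mc_amp, self.im_amp, self.ao_amp) <= 0:
            raise ConfigurationError("SCG component amplitudes must be positive")
        if not 0.0 < self.im_fraction < 1.0:
            raise ConfigurationError("im_fraction must lie in (0, 1)")
        sim = abs(self.mc_amp - self.ao_amp) / max(self.mc_amp, self.ao_amp)
        if sim > 0.2:
            raise ConfigurationError(
                f"MC and AO amplitudes differ by {sim:.0%}; must be within 20% "
                "to pose the disambiguation problem")


@dataclass
class GroundTruth:
    """Per-beat truth retained from the noiseless templates."""

    beat_times_s: np.ndarray
    ibis_ms: np.ndarray
    spg: dict[str, np.ndarray]       # onset, max_slope, systolic, notch, diastolic (s)
    scg: dict[str, np.ndarray]       # mc, im, ao (s)
    pat_ms: np.ndarray
    ptt_ms: np.ndarray
    hr_bpm: np.ndarray
    rmssd_ms: float

    def __post_init__(self) -> None:
        if np.any(self.pat_ms <= self.ptt_ms) or np.any(self.ptt_ms <= 0):
            raise ConfigurationError("ground truth requires PAT > PTT > 0 per beat")

    def to_json_dict(self) -> dict:
        def arr(a):
            return [None if np.isnan(v) else float(v) for v in np.asarray(a, dtype=float)]
        return {
            "beat_times_s": arr(self.beat_times_s),
            "ibis_ms": arr(self.ibis_ms),
            "spg": {k: arr(v) for k, v in self.spg.items()},
            "scg": {k: arr(v) for k, v in self.scg.items()},
            "pat_ms": arr(self.pat_ms),
            "ptt_ms": arr(self.ptt_ms),
            "hr_bpm": arr(self.hr_bpm),
            "rmssd_ms": float(self.rmssd_ms),
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "GroundTruth":
        def arr(a):
            return np.array([np.nan if v is None else v for v in a], dtype=float)
        return cls(
            beat_times_s=arr(data["beat_times_s"]),
            ibis_ms=arr(data["ibis_ms"]),
            spg={k: arr(v) for k, v in data["spg"].items()},
            scg={k: arr(v) for k, v in data["scg"].items()},
            pat_ms=arr(data["pat_ms"]),
            ptt_ms=arr(data["ptt_ms"]),
            hr_bpm=arr(data["hr_bpm"]),
            rmssd_ms=float(data["rmssd_ms"]),
        )


@dataclass(frozen=True)
class RecordingConfig:
    """Study conditions for one synthetic recording.

    Defaults are the measurement conditions of the sensing platform: 25 kHz
    synchronous sampling, 70 BPM with 30 ms RMSSD, normal-blood-pressure
    PAT/PTT of 222.8/152.4 ms, 50 µε peak pulse strain, 400 aF sensor noise,
    14-bit quantization, and a 10 µε respiratory baseline drift.
    """

    duration_s: float = 30.0
    fs_hz: float = 25_000.0
    hr_mean_bpm: float = 70.0
    rmssd_ms: float = 30.0
    pat_ms: float = 222.8
    ptt_ms: float = 152.4
    peak_strain_ue: float = 50.0
    noise_rms_aF: float = 400.0
    adc_bits: int = 14
    scg_noise_rms: float = 0.02
    drift_mode: str | None = "respiratory"
    drift_amplitude_ue: float = 10.0
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    scg_shape: ScgShape = field(default_factory=ScgShape)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticRecording:
    """Paired SPG/SCG count traces plus their ground truth."""

    spg_counts: SignalTrace
    scg_counts: SignalTrace
    ground_truth: GroundTruth
    config: RecordingConfig
    seed: int

    def __post_init__(self) -> None:
        if self.spg_counts.n_samples != self.scg_counts.n_samples or \
                self.spg_counts.fs_hz != self.scg_counts.fs_hz:
            raise ConfigurationError("SPG and SCG channels must be synchronous")


# ---------------------------------------------------------------------------
# beat schedule
# ---------------------------------------------------------------------------

_PLAN_START_S = 0.2  # first scored beat; one mean IBI is reserved at each end


def generate_beat_times(duration_s: float, hr_mean_bpm: float = 70.0,
                        rmssd_ms: float = 30.0,
                        rng_seed: int | np.random.SeedSequence = 0) -> BeatPlan:
    """Draw a beat schedule whose realized RMSSD matches the target exactly.

    Inter-beat intervals are the mean IBI (60000/HR ms) plus i.i.d. zero-mean
    Gaussian jitter; because RMSSD is linear in the jitter scale, the jitter
    is rescaled post hoc so the realized RMSSD of the emitted sequence equals
    ``rmssd_ms`` (to float precision).  No autocorrelation structure is
    claimed.  Intervals outside [300, 2000] ms raise a configuration error.
    """
    if rmssd_ms < 0:
        raise ConfigurationError("rmssd_ms must be non-negative")
    if not hr_mean_bpm > 0:
        raise ConfigurationError("hr_mean_bpm must be positive")
    mean_ibi_ms = 60_000.0 / hr_mean_bpm
    mean_ibi_s = mean_ibi_ms / 1000.0
    if not duration_s > 2.0 * mean_ibi_s:
        raise ConfigurationError("duration must exceed two mean inter-beat intervals")
    lo, hi = IBI_BOUNDS_MS
    if mean_ibi_ms - 5.0 * rmssd_ms < lo or mean_ibi_ms + 5.0 * rmssd_ms > hi:
        raise ConfigurationError(
            f"target RMSSD {rmssd_ms} ms infeasible for mean IBI {mean_ibi_ms:.0f} ms "
            f"within [{lo:.0f}, {hi:.0f}] ms")

    n_ibis = int(np.floor((duration_s - _PLAN_START_S - mean_ibi_s) / mean_ibi_s))
    if n_ibis < 2:
        raise ConfigurationError("duration too short for at least three beats")
    rng = np.random.default_rng(rng_seed)
    jitter = rng.normal(0.0, rmssd_ms / np.sqrt(2.0), size=n_ibis) if rmssd_ms > 0 \
        else np.zeros(n_ibis)
    jitter -= jitter.mean()
    if rmssd_ms > 0:
        realized = float(np.sqrt(np.mean(np.diff(jitter) ** 2)))
        if realized == 0.0:
            raise ConfigurationError("degenerate jitter draw; use a different seed")
        jitter *= rmssd_ms / realized
    ibis_ms = mean_ibi_ms + jitter
    if np.any(ibis_ms < lo) or np.any(ibis_ms > hi):
        raise ConfigurationError("drawn inter-beat intervals leave the physiological band")
    beat_times = _PLAN_START_S + np.concatenate(([0.0], np.cumsum(ibis_ms) / 1000.0))
    return BeatPlan(beat_times_s=beat_times, ibis_ms=ibis_ms,
                    target_hr_bpm=hr_mean_bpm, target_rmssd_ms=rmssd_ms)


def _extended_beat_times(plan: BeatPlan) -> np.ndarray:
    """Scored beats plus one lead-in and one lead-out template beat."""
    t = plan.beat_times_s
    return np.concatenate(([t[0] - plan.mean_ibi_s], t, [t[-1] + plan.mean_ibi_s]))


# ---------------------------------------------------------------------------
# SPG channel
# ---------------------------------------------------------------------------

def _fine_grid(duration_s: float, fs_hz: float, oversample: int) -> tuple[int, int, float]:
    n = int(round(duration_s * fs_hz))
    fine_n = (n - 1) * oversample + 1
    return n, fine_n, fs_hz * oversample


def _add_gaussian(fine: np.ndarray, fs_fine: float, amp: float, center_s: float,
                  width_s: float) -> None:
    # 6 sigma: the truncation step must stay below the per-sample increment on
    # the oversampled grid, or derivative-based fiducials snap to lobe edges
    half = 6.0 * width_s
    i0 = max(0, int(np.ceil((center_s - half) * fs_fine)))
    i1 = min(fine.size, int(np.floor((center_s + half) * fs_fine)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs_fine
    fine[i0:i1] += amp * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def synth_spg(plan: BeatPlan, shape: PulseShape, fs_hz: float,
              duration_s: float | None = None, peak_strain_ue: float = 50.0,
              oversample: int = 10) -> tuple[SignalTrace, dict[str, np.ndarray]]:
    """Synthesize the noiseless SPG strain waveform and its true fiducials.

    Returns the trace in µε (peak scaled to ``peak_strain_ue``) and a dict of
    per-scored-beat fiducial times in seconds with keys ``onset``,
    ``max_slope``, ``systolic``, ``notch``, ``diastolic``.  Fiducials are
    located on the ``oversample``× fine grid of the noiseless template; a
    missing extremum (degenerate shape) is reported as NaN.
    """
    if fs_hz < 4.0 / shape.min_width_s():
        raise ConfigurationError(
            f"sampling rate {fs_hz} Hz below twice the pulse bandwidth")
    if duration_s is None:
        duration_s = plan.beat_times_s[-1] + 2.0 * plan.mean_ibi_s
    n, fine_n, fs_fine = _fine_grid(duration_s, fs_hz, oversample)
    fine = np.zeros(fine_n)
    for t_b in _extended_beat_times(plan):
        for amp, delay, width in shape.components():
            if amp != 0.0:
                _add_gaussian(fine, fs_fine, amp, t_b + delay, width)
    peak = fine.max()
    if peak > 0:
        fine *= peak_strain_ue / peak

    def f_idx(t_s: float) -> int:
        return int(np.clip(round(t_s * fs_fine), 0, fine_n - 1))

    fid = {k: np.full(plan.n_beats, np.nan)
           for k in ("onset", "max_slope", "systolic", "notch", "diastolic")}
    for b, t_b in enumerate(plan.beat_times_s):
        s0, s1 = f_idx(t_b), f_idx(t_b + shape.systolic_delay_s + 0.18)
        sys_f = s0 + int(np.argmax(fine[s0:s1 + 1]))
        fid["systolic"][b] = sys_f / fs_fine
        o0 = f_idx(t_b - 0.25)
        onset_f = o0 + int(np.argmin(fine[o0:sys_f + 1]))
        fid["onset"][b] = onset_f / fs_fine
        if sys_f > onset_f:
            slope = np.diff(fine[onset_f:sys_f + 1])
            fid["max_slope"][b] = (onset_f + int(np.argmax(slope))) / fs_fine
        seg = fine[sys_f:f_idx(sys_f / fs_fine + 0.55) + 1]
        mins, _ = find_peaks(-seg)
        if mins.size:
            notch_f = sys_f + mins[0]
            fid["notch"][b] = notch_f / fs_fine
            maxs, _ = find_peaks(seg)
            later = maxs[maxs > mins[0]]
            if later.size:
                fid["diastolic"][b] = (sys_f + later[0]) / fs_fine
    trace = SignalTrace(fine[::oversample], fs_hz=fs_hz, units="ue")
    return trace, fid


# ---------------------------------------------------------------------------
# SCG channel
# ---------------------------------------------------------------------------

def synth_scg(plan: BeatPlan, shape: ScgShape, pat_ms: float, ptt_ms: float,
              fs_hz: float, duration_s: float | None = None,
              systolic_times_s: np.ndarray | None = None,
              oversample: int = 10) -> tuple[SignalTrace, dict[str, np.ndarray]]:
    """Synthesize the SCG channel (arbitrary units) and its true fiducials.

    For each beat, MC is placed at (systolic − PAT), AO at (systolic − PTT)
    and IM between them at ``shape.im_fraction`` of the MC→AO span.  If
    ``systolic_times_s`` is omitted, systolic times default to beat time plus
    the default systolic delay.  Returned dict keys: ``mc``, ``im``, ``ao``
    (times in s) plus per-beat ``pat_ms``/``ptt_ms`` (configured values).
    """
    if not pat_ms > ptt_ms > 0:
        raise ConfigurationError("require PAT > PTT > 0")
    min_ibi_ms = float(np.min(plan.ibis_ms))
    if pat_ms >= min_ibi_ms:
        raise ConfigurationError(
            f"PAT {pat_ms} ms exceeds the shortest inter-beat interval {min_ibi_ms:.0f} ms")
    if fs_hz < 4.0 * shape.carrier_hz:
        raise ConfigurationError("sampling rate too low for the SCG carrier")
    if duration_s is None:
        duration_s = plan.beat_times_s[-1] + 2.0 * plan.mean_ibi_s
    if systolic_times_s is None:
        systolic_times_s = plan.beat_times_s + PulseShape().systolic_delay_s
    systolic_times_s = np.asarray(systolic_times_s, dtype=float)
    if systolic_times_s.size != plan.n_beats:
        raise ConfigurationError("one systolic time per scored beat required")

    sys_offset = float(np.mean(systolic_times_s - plan.beat_times_s))
    ext = _extended_beat_times(plan)
    all_sys = np.concatenate(([ext[0] + sys_offset], systolic_times_s,
                              [ext[-1] + sys_offset]))

    n, fine_n, fs_fine = _fine_grid(duration_s, fs_hz, oversample)
    fine = np.zeros(fine_n)
    w = shape.component_width_s
    half = 6.0 * w

    def add_wavelet(amp: float, center: float) -> None:
        i0 = max(0, int(np.ceil((center - half) * fs_fine)))
        i1 = min(fine_n, int(np.floor((center + half) * fs_fine)) + 1)
        if i1 <= i0:
            return
        t = np.arange(i0, i1) / fs_fine - center
        fine[i0:i1] += amp * np.exp(-0.5 * (t / w) ** 2) * np.cos(2 * np.pi * shape.carrier_hz * t)

    centers = {"mc": [], "im": [], "ao": []}
    for sys_t in all_sys:
        mc_t = sys_t - pat_ms / 1000.0
        ao_t = sys_t - ptt_ms / 1000.0
        im_t = mc_t + shape.im_fraction * (ao_t - mc_t)
        add_wavelet(shape.mc_amp, mc_t)
        add_wavelet(shape.im_amp, im_t)
        add_wavelet(shape.ao_amp, ao_t)
        centers["mc"].append(mc_t)
        centers["im"].append(im_t)
        centers["ao"].append(ao_t)

    def refine(center: float) -> float:
        i0 = max(0, int(round((center - 1.5 * w) * fs_fine)))
        i1 = min(fine_n, int(round((center + 1.5 * w) * fs_fine)) + 1)
        return (i0 + int(np.argmax(fine[i0:i1]))) / fs_fine

    nb = plan.n_beats
    fid = {k: np.array([refine(c) for c in centers[k][1:1 + nb]]) for k in ("mc", "im", "ao")}
    fid["pat_ms"] = np.full(nb, float(pat_ms))
    fid["ptt_ms"] = np.full(nb, float(ptt_ms))
    trace = SignalTrace(fine[::oversample], fs_hz=fs_hz, units="au")
    return trace, fid


# ---------------------------------------------------------------------------
# drift and composition
# ---------------------------------------------------------------------------

def add_baseline_drift(trace: SignalTrace, mode: str, amplitude_ue: float,
                       rng_seed: int | np.random.SeedSequence = 0) -> SignalTrace:
    """Superimpose slow baseline drift on a trace.

    ``respiratory`` adds a sinusoid with a seeded random frequency in
    0.2–0.35 Hz and random phase, peak amplitude ``amplitude_ue`` (so the
    drift is bounded by ±amplitude).  ``grip`` adds a seeded smooth random
    walk — white noise low-pass filtered at 0.5 Hz — scaled to an RMS of
    amplitude/3, emulating grip-pressure variation with excursions up to
    roughly the stated amplitude.  Zero amplitude returns the input unchanged.
    """
    if amplitude_ue == 0:
        return trace.with_values(trace.values.copy())
    rng = np.random.default_rng(rng_seed)
    t = trace.times()
    if mode == "respiratory":
        f = rng.uniform(0.2, 0.35)
        phase = rng.uniform(0, 2 * np.pi)
        drift = amplitude_ue * np.sin(2 * np.pi * f * t + phase)
    elif mode == "grip":
        white = rng.normal(0.0, 1.0, size=trace.n_samples)
        sos = butter(2, 0.5, btype="lowpass", fs=trace.fs_hz, output="sos")
        drift = sosfiltfilt(sos, white)
        rms = float(np.sqrt(np.mean(drift**2)))
        drift = drift / rms * (amplitude_ue / 3.0) if rms > 0 else drift
    else:
        raise ConfigurationError(f"unknown drift mode {mode!r}")
    return trace.with_values(trace.values + drift)


def default_scg_channel_params(fs_hz: float, noise_rms: float = 0.02,
                               adc_bits: int = 14) -> SensorParams:
    """Acquisition stage for the SCG channel (arbitrary units).

    The seismometer channel has no strain calibration; it is modeled as a
    linear gain of 1000 counts-equivalent per unit, a ±4-unit clip range,
    additive white noise of ``noise_rms`` units RMS and the same N-bit
    quantizer as the strain channel.
    """
    gain = 1000.0
    return SensorParams(sensitivity_aF_per_ue=gain, c0_aF=1.0, linear_range_ue=4.0,
                        noise_rms_aF=noise_rms * gain, adc_bits=adc_bits,
                        sampling_rate_hz=fs_hz)


def make_recording(config: RecordingConfig,
                   rng_seed: int = 0) -> SyntheticRecording:
    """Generate one fully deterministic paired recording.

    Composes beat plan → SPG/SCG templates (ground truth captured here) →
    baseline drift → sensor transduction (gain, saturation, noise,
    quantization) per channel.  All randomness derives from ``rng_seed`` via
    independent spawned streams.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_plan, s_drift, s_spg, s_scg = ss.spawn(4)
    plan = generate_beat_times(config.duration_s, config.hr_mean_bpm,
                               config.rmssd_ms, rng_seed=s_plan)
    spg_ue, spg_fid = synth_spg(plan, config.pulse_shape, config.fs_hz,
                                duration_s=config.duration_s,
                                peak_strain_ue=config.peak_strain_ue)
    scg_au, scg_fid = synth_scg(plan, config.scg_shape, config.pat_ms, config.ptt_ms,
                                config.fs_hz, duration_s=config.duration_s,
                                systolic_times_s=spg_fid["systolic"])
    if config.drift_mode:
        spg_ue = add_baseline_drift(spg_ue, config.drift_mode,
                                    config.drift_amplitude_ue, rng_seed=s_drift)
    spg_sensor = SensorParams(noise_rms_aF=config.noise_rms_aF,
                              adc_bits=config.adc_bits,
                              sampling_rate_hz=config.fs_hz)
    spg_counts = transduce(spg_ue, spg_sensor, rng_seed=s_spg)
    scg_sensor = default_scg_channel_params(config.fs_hz, config.scg_noise_rms,
                                            config.adc_bits)
    scg_counts = transduce(scg_au, scg_sensor, rng_seed=s_scg)
    gt = GroundTruth(
        beat_times_s=plan.beat_times_s,
        ibis_ms=plan.ibis_ms,
        spg={k: spg_fid[k] for k in ("onset", "max_slope", "systolic", "notch", "diastolic")},
        scg={k: scg_fid[k] for k in ("mc", "im", "ao")},
        pat_ms=scg_fid["pat_ms"],
        ptt_ms=scg_fid["ptt_ms"],
        hr_bpm=60_000.0 / plan.ibis_ms,
        rmssd_ms=plan.realized_rmssd_ms(),
    )
    return SyntheticRecording(spg_counts=spg_counts, scg_counts=scg_counts,
                              ground_truth=gt, config=config, seed=int(rng_seed))


def write_recording(rec: SyntheticRecording, out_dir: str | Path) -> dict[str, Path]:
    """Export a recording: two CSV traces (+ sidecars) and one JSON ground-truth file.

    The JSON file also embeds the configuration snapshot and seed so a run is
    reproducible from its outputs alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spg": write_trace(rec.spg_counts, out_dir / "spg.csv"),
        "scg": write_trace(rec.scg_counts, out_dir / "scg.csv"),
    }
    payload = {
        "seed": rec.seed,
        "config": rec.config.as_dict(),
        "ground_truth": rec.ground_truth.to_json_dict(),
    }
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(payload, indent=1))
    paths["ground_truth"] = truth_path
    return paths
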