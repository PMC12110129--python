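# Methods

## Sensor model

The strain sensor is modeled at the level of its published calibration
constants, not its geometry: a differential capacitance transfer
ΔC(δd) = ε₀A/(d₀−δd) − ε₀A/(d₀+δd) (exactly odd; the `linearized` mode keeps
the first-order term 2ε₀A·δd/d₀²), a prismatic-beam strain ε = δL/L_b, and
the cantilever calibration relation ε = 3t_c·δy·(L_c−d)/(2L_c³).  The
position d is measured **from the fixed end**, so strain is maximal at d = 0
and zero at the free end where the bending moment vanishes; this matches the
physical mounting (sensor bonded near the fixed end) even though the
formula is sometimes quoted with d described loosely as a distance "to the
end" of the beam.

The forward simulator (`transduce`) maps a strain waveform to ADC counts:
hard clipping at the ±linear range (the measured compression is
ASIC-limited and no curve is published, so saturation is the simplest
faithful choice), gain S, additive white Gaussian capacitance noise, and
uniform quantization.  The ADC full scale defaults to
±(S·linear_range + 6·noise_rms) so the linear range plus noise excursions
map inside the code space; the 14-bit LSB is then ≈ 27 aF.  Noise is white
at the capacitance level and not band-limited: every downstream consumer
immediately band-passes, so sensor-side shaping would be unobservable.
Units are aF and µε throughout the API (SI only inside the physics), which
keeps floats near unity and matches how such sensors are reported.

Default constants: S = 316 aF/µε, C₀ = 8.8 pF (4 × 2.2 pF), linear range
±700 µε, noise 400 aF RMS, 14-bit ADC, 25 kHz sampling.  These give a
system gauge factor ≈ 36, a noise-equivalent resolution ≈ 1.27 µε and a
40 µs timing resolution — the operating point every simulation in this
package uses unless overridden.

## Synthetic recordings

The generator emulates the *measurement conditions*, not hemodynamics: no
Windkessel model, no respiration–HR coupling, no motion artifacts beyond
baseline drift.

**Beat schedule.**  Inter-beat intervals are mean 60000/HR ms plus i.i.d.
zero-mean Gaussian jitter.  Because RMSSD is linear in the jitter scale, the
jitter is rescaled post hoc so the realized RMSSD equals the target exactly;
no autocorrelation structure is claimed, which is the main way the schedule
is simpler than real sinus rhythm (no respiratory sinus arrhythmia, no
trends).  Intervals outside 300–2000 ms raise an error.  Defaults: 70 BPM,
RMSSD 30 ms.

**SPG waveform.**  Each pulse is a sum of Gaussian lobes: systolic (delay
130 ms, width 50 ms), second-systolic shoulder (230/70 ms, amplitude 0.40),
a narrow negative notch lobe (300/25 ms, depth 0.10), diastolic wave
(360/80 ms, amplitude 0.30) and a broad low "runoff" lobe (500/220 ms,
amplitude 0.15) standing in for the slow diastolic pressure decay.  The
runoff matters structurally: it makes the pre-upstroke trough a genuine
local minimum, so the onset fiducial is well defined.  The template peak is
scaled to 50 µε.  Gaussians are evaluated over ±6σ windows — wide enough
that the truncation step is smaller than the per-sample increment of the
oversampled grid; with narrower windows, derivative-based fiducials snap to
lobe edges.

**SCG waveform.**  MC, IM and AO are Gabor wavelets (Gaussian envelope
σ = 8 ms, 25 Hz cosine carrier, peak exactly at the component center).  MC
is placed at systolic − PAT, AO at systolic − PTT, IM midway.  Amplitudes
0.60/1.00/0.55: IM is the tallest so a high-threshold pass isolates it,
while MC and AO differ by under 10% — enforced ≤ 20% by the config — so the
amplitude-ambiguity the two-pass labeling resolves is actually present.
The channel is in arbitrary units with its own noise scale (2% of the S1
peak by default) because the seismometer has no strain calibration.

**Fiducial ground truth** is located numerically on a 10× oversampled grid
of the noiseless template before drift, noise or quantization are applied;
per-beat PAT/PTT ground truth equals the configured values by construction.
One template beat is prepended and appended around the scored plan so edge
beats have a preceding trough and complete SCG segments; lead beats are not
scored.

**Drift.**  Respiratory mode: a sinusoid with seeded random frequency in
0.2–0.35 Hz, bounded by ± amplitude.  Grip mode: white noise low-passed at
0.5 Hz, scaled to RMS = amplitude/3 (so excursions reach roughly the stated
amplitude while the marginal RMS is seed-independent).

Because the generator's beats are smooth, symmetric-lobed and noise is
white, passing recovery tests demonstrates the correctness and internal
consistency of the processing chain under the stated noise and drift — not
robustness to arrhythmia, waveform morphology drift, or contact artifacts
beyond the grip model.

## Processing chain

All filters are 2nd-order Butterworth band-passes applied
forward-backward (`sosfiltfilt`).  Zero-phase application is the only
defensible choice offline: PAT/PTT are single-millisecond-scale timing
measurements and a causal filter would bias every fiducial late.

Peak detection is `scipy.signal.find_peaks` with a refractory spacing
(default 0.3 s) and a scale-free prominence floor.  The reference scale
differs by signal statistics, and this is a deliberate design point:

- **SPG systolic peaks**: 0.1 × interquartile range.  The pulse occupies the
  whole beat, so the IQR is a stable fraction of the amplitude.
- **SPG onsets** (minima of the negated trace): 0.25 × peak-to-peak span.
  The onset trough's prominence is of the order of the full pulse height
  while the dicrotic notch's is only its depth; a quantile-based floor
  admits notch dips whenever they fall outside the refractory window.
- **APG peaks**: 0.15 × span; differentiation amplifies broadband noise and
  the APG's IQR sits at the inter-beat noise floor.
- **SCG IM pass**: 0.3 × span, **MC/AO pass**: 0.05 × span.  SCG is sparse
  and spiky — quartiles of a normalized SCG trace collapse to the noise
  floor, so the span is the robust scale.  The 0.3/0.05 factors realize the
  qualitative "high threshold, then lowered threshold" two-pass scheme; all
  factors are exposed as parameters.

Baseline removal interpolates linearly through the (onset, value) anchors
with constant extrapolation beyond the first/last onset; it zeroes the trace
at every onset exactly and is idempotent for fixed onsets.  Normalization is
a global min-max map to [0, 1] (per-beat normalization would break the
single time base that PAT/PTT need).  The APG is the *first* derivative of
the normalized SPG — the convention of this application, noted as differing
from the second-derivative definition common elsewhere — computed as a
central difference after a short moving average (5 samples at 1 kHz, scaled
with the sampling rate) because raw differentiation of quantized data is
noise-dominated.

Segmentation uses half-open IM-to-IM spans (n IM peaks → n−1 segments, no
double counting).  Within a segment the first lowered-threshold peak after
the opening IM is labeled AO of the previous heartbeat and the last peak
before the closing IM is MC of the current heartbeat; segments with fewer
than two interior peaks are flagged and excluded from timing metrics.  All
SCG detection runs on the positive normalized trace; polarity is a
parameter for recordings with the opposite convention.

## Metrics

HR is 60000/PPI per interval, gated to (20, 300) BPM.  RMSSD is computed on
intervals in ms (not on BPM values — RMSSD is defined on intervals, and the
symmetric HRV accuracy is scale-free either way).  Modalities are paired by
greedy nearest-neighbour matching within ± half the median reference
interval; the agreement report (AVG, MAE, ME, SD, RMSE and the
normalized-RMSE accuracy) is computed beat-wise over matched interval pairs
with the reference modality's mean as AVG.  HRV agreement is evaluated on
the matched beat subset of each pairing so that both RMSSDs cover the same
heartbeats; an edge beat detected in only one modality would otherwise bias
the comparison.  For PAT/PTT each systolic peak is paired with the latest
preceding MC and AO within 600 ms; non-positive or over-window intervals
are excluded and counted.  SD columns use the sample standard deviation
(ddof = 1), which gives the exact identity RMSE² = ME² + SD²·(n−1)/n.

## Problem sizes and numerical choices

Unit tests generate at 1 kHz (a documented departure from the 25 kHz
production rate; all timing outputs are in seconds/ms so results are
rate-independent to within one sample period).  The end-to-end recovery
checks and `scripts/acceptance.py` run at 25 kHz: 20 × 30 s recordings for
the HR/HRV medians and one 60 s recording (≈ 68 beats) for PAT/PTT, which
completes in well under a minute on one CPU.  All randomness flows from a
single integer seed through independent spawned generator streams (beat
jitter, drift, per-channel noise); identical seeds give bit-identical
recordings.

## Known limitations

- No dicrotic-notch or diastolic-peak *detectors*: those fiducials exist in
  the generator's ground truth but are not used for estimation.
- The first onset of a recording can be lost to the filter's start-up edge;
  edge beats are generally the least reliable and the metrics tolerate
  their loss through matching.
- The frequency content of the SCG model is a single 25 Hz carrier; real S1
  complexes are broader band.
- No blood-pressure regression from PAT/PTT, and no frequency-domain HRV.
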