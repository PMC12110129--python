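"""End-to-end processing: raw two-channel counts → fiducials → reports.

Thin composition layer over :mod:`spg_processing`, :mod:`scg_processing` and
:mod:`cardio_metrics`; this is what the CLI, the analysis scripts and the
acceptance checks call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cardio_metrics as cm
from . import scg_processing as scg
from . import spg_processing as spg
from .traces import SignalTrace

__all__ = ["SpgAnalysis", "ScgAnalysis", "RecordingAnalysis",
           "process_spg", "process_scg", "analyze_recording"]


@dataclass
class SpgAnalysis:
    """Intermediate and final products of the SPG chain."""

    normalized: SignalTrace
    apg: SignalTrace
    onset_idx: np.ndarray
    systolic_idx: np.ndarray
    apg_peak_idx: np.ndarray
    fs_hz: float

    @property
    def systolic_times_s(self) -> np.ndarray:
        return self.systolic_idx / self.fs_hz

    @property
    def apg_peak_times_s(self) -> np.ndarray:
        return self.apg_peak_idx / self.fs_hz

    @property
    def onset_times_s(self) -> np.ndarray:
        return self.onset_idx / self.fs_hz


@dataclass
class ScgAnalysis:
    normalized: SignalTrace
    im_idx: np.ndarray
    mc_idx: np.ndarray
    ao_idx: np.ndarray
    n_flagged: int
    fs_hz: float

    @property
    def mc_times_s(self) -> np.ndarray:
        return self.mc_idx / self.fs_hz

    @property
    def ao_times_s(self) -> np.ndarray:
        return self.ao_idx / self.fs_hz

    @property
    def im_times_s(self) -> np.ndarray:
        return self.im_idx / self.fs_hz


@dataclass
class RecordingAnalysis:
    """Two-channel analysis: fiducials, HR/HRV agreement and PAT/PTT."""

    spg: SpgAnalysis
    scg: ScgAnalysis
    hr_reports: dict[str, cm.AgreementReport] = field(default_factory=dict)
    hrv_rmssd_ms: dict[str, float] = field(default_factory=dict)
    hrv_accuracy_pct: dict[str, float] = field(default_factory=dict)
    pat_ptt: cm.PatPttReport | None = None


def process_spg(trace: SignalTrace, min_ibi_s: float = 0.3,
                filter_spec: spg.FilterSpec | None = None) -> SpgAnalysis:
    """Run the full SPG chain on a raw (counts or strain) trace."""
    spec = filter_spec or spg.FilterSpec()
    filtered = spg.bandpass(trace, spec)
    onsets = spg.detect_onsets(filtered, min_ibi_s=min_ibi_s)
    detrended = spg.remove_baseline(filtered, onsets) if onsets.size >= 2 else filtered
    norm = spg.normalize(detrended)
    systolic = spg.detect_systolic_peaks(norm, min_ibi_s=min_ibi_s)
    apg = spg.derive_apg(norm)
    apg_peaks = spg.detect_apg_peaks(apg, min_ibi_s=min_ibi_s)
    return SpgAnalysis(normalized=norm, apg=apg, onset_idx=onsets,
                       systolic_idx=systolic, apg_peak_idx=apg_peaks,
                       fs_hz=trace.fs_hz)


def process_scg(trace: SignalTrace, min_ibi_s: float = 0.3) -> ScgAnalysis:
    """Run the SCG chain: preprocess, IM pass, segmentation, MC/AO pass."""
    norm = scg.preprocess_scg(trace)
    im = scg.detect_im_peaks(norm, min_ibi_s=min_ibi_s)
    segments = scg.segment_beats(norm, im)
    result = scg.detect_mc_ao(norm, segments)
    return ScgAnalysis(normalized=norm, im_idx=im, mc_idx=result.mc_idx,
                       ao_idx=result.ao_idx, n_flagged=result.n_flagged,
                       fs_hz=trace.fs_hz)


def analyze_recording(spg_trace: SignalTrace, scg_trace: SignalTrace,
                      min_ibi_s: float = 0.3) -> RecordingAnalysis:
    """Process both channels and assemble the agreement and timing reports.

    HR agreement is reported for SPG-vs-SCG and APG-vs-SCG (SCG AO peaks as
    the reference) and SPG-vs-APG (APG as reference).  HRV (RMSSD on PPIs)
    and its pairwise accuracy use the same fiducials.  PAT/PTT pair each SPG
    systolic peak with the latest preceding MC/AO.
    """
    sa = process_spg(spg_trace, min_ibi_s=min_ibi_s)
    ca = process_scg(scg_trace, min_ibi_s=min_ibi_s)
    out = RecordingAnalysis(spg=sa, scg=ca)

    times = {
        "SPG": sa.systolic_times_s,
        "APG": sa.apg_peak_times_s,
        "SCG": ca.ao_times_s,
    }
    pairings = [("SPG", "SCG"), ("APG", "SCG"), ("SPG", "APG")]
    for test, ref in pairings:
        key = f"{test}-{ref}"
        try:
            out.hr_reports[key] = cm.compare_hr(times[test], times[ref],
                                                modalities=(test, ref))
        except cm.DomainError:
            pass
    for name, t in times.items():
        if t.size >= 3:
            out.hrv_rmssd_ms[name] = cm.rmssd(cm.ppi_from_peaks(t))
    # HRV agreement is computed on the matched beat subset of each pairing so
    # that both RMSSDs cover the same heartbeats (an edge beat detected in only
    # one modality would otherwise bias the comparison).
    for test, ref in pairings:
        pairs = cm.match_beats(times[test], times[ref])
        if len(pairs) < 3:
            continue
        tt = times[test][[i for i, _ in pairs]]
        rt = times[ref][[j for _, j in pairs]]
        out.hrv_accuracy_pct[f"{test}-{ref}"] = cm.hrv_accuracy(
            cm.rmssd(cm.ppi_from_peaks(tt)), cm.rmssd(cm.ppi_from_peaks(rt)))
    try:
        out.pat_ptt = cm.compute_pat_ptt(sa.systolic_times_s, ca.mc_times_s,
                                         ca.ao_times_s)
    except cm.DomainError:
        out.pat_ptt = None
    return out
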