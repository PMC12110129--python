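"""SCG conditioning and the two-pass MC/AO disambiguation.

The S1 complex of a seismocardiogram contains the mitral-closure (MC) peak,
the isovolumic-moment (IM) point and the aortic-opening (AO) peak.  MC and AO
have similar amplitudes, so one-shot peak detection cannot label them.  The
chain here: band-pass 0.5–80 Hz (2nd-order Butterworth, zero-phase) and
min-max normalize; detect the tall IM peaks with a high prominence threshold;
segment the trace into IM-to-IM heartbeat segments; re-run peak detection in
each segment with a lowered threshold, so that the first peak after the
opening IM is the AO of the previous heartbeat and the last peak before the
closing IM is the MC of the current heartbeat.

Prominence thresholds are expressed as fractions of the normalized trace's
peak-to-peak span (IM pass 0.3, MC/AO pass 0.05), both config-exposed.  The
sparse, spiky nature of SCG makes quantile-based scales collapse to the noise
floor, so the full span is the robust scale here.  All peaks are detected on
the positive normalized trace (IM modeled positive); pass ``polarity=-1`` to
flip if a recording's convention differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError
from .spg_processing import FilterSpec, bandpass, normalize
from .traces import SignalTrace

__all__ = [
    "ScgBeatSegment",
    "McAoResult",
    "preprocess_scg",
    "detect_im_peaks",
    "segment_beats",
    "detect_mc_ao",
]

log = logging.getLogger(__name__)


@dataclass
class ScgBeatSegment:
    """One IM-to-IM heartbeat segment (half-open, [start, end)).

    ``ao_prev_idx`` is the AO peak of the heartbeat that opens the segment;
    ``mc_idx`` is the MC peak of the heartbeat that closes it; either is −1
    when the beat is flagged.
    """

    start_idx: int
    end_idx: int
    im_idx: int
    mc_idx: int = -1
    ao_prev_idx: int = -1
    flagged: bool = False


@dataclass
class McAoResult:
    """Flat MC/AO index arrays plus the per-segment labeling."""

    mc_idx: np.ndarray
    ao_idx: np.ndarray
    segments: list[ScgBeatSegment]

    @property
    def n_flagged(self) -> int:
        return sum(s.flagged for s in self.segments)


def preprocess_scg(trace: SignalTrace, low_hz: float = 0.5, high_hz: float = 80.0,
                   order: int = 2) -> SignalTrace:
    """Band-pass (default 0.5–80 Hz, zero-phase) then min-max normalize."""
    if trace.fs_hz < 2.0 * high_hz:
        raise ConfigurationError(
            f"sampling rate {trace.fs_hz} Hz below 2x the SCG band edge {high_hz} Hz")
    spec = FilterSpec(low_hz=low_hz, high_hz=high_hz, order=order, zero_phase=True)
    return normalize(bandpass(trace, spec))


def detect_im_peaks(trace: SignalTrace, min_ibi_s: float = 0.3,
                    prominence_frac: float = 0.3, polarity: int = 1) -> np.ndarray:
    """First pass: one IM peak per heartbeat.

    High prominence floor (``prominence_frac`` × trace span) plus a
    refractory spacing of ``min_ibi_s``; because MC/IM/AO lie within tens of
    milliseconds of each other, the spacing constraint alone retains only the
    tallest component of each S1 complex.
    """
    x = polarity * trace.values
    if x.size == 0 or np.ptp(x) == 0:
        return np.empty(0, dtype=int)
    prom = prominence_frac * float(np.ptp(x))
    distance = max(1, int(round(min_ibi_s * trace.fs_hz)))
    idx, _ = find_peaks(x, prominence=prom, distance=distance)
    return idx


def segment_beats(trace: SignalTrace, im_indices: np.ndarray) -> list[ScgBeatSegment]:
    """Half-open IM-to-IM segments; n IM peaks yield n−1 segments.

    Segment k spans [IM_k, IM_{k+1}); its ``im_idx`` is the closing IM (the
    current heartbeat's).  Fewer than two IM peaks yield an empty list with a
    warning.
    """
    im = np.asarray(im_indices, dtype=int)
    if im.size < 2:
        log.warning("cannot segment: %d IM peak(s) found", im.size)
        return []
    return [ScgBeatSegment(start_idx=int(a), end_idx=int(b), im_idx=int(b))
            for a, b in zip(im[:-1], im[1:])]


def detect_mc_ao(trace: SignalTrace, segments: list[ScgBeatSegment],
                 prominence_frac: float = 0.05, polarity: int = 1) -> McAoResult:
    """Second pass: lowered-threshold detection inside each segment.

    Within [IM_k, IM_{k+1}) the first detected peak after the opening IM is
    labeled AO of the previous heartbeat and the last detected peak before
    the closing IM is labeled MC of the current heartbeat.  Segments with
    fewer than two interior peaks are flagged and excluded from PAT/PTT use.
    Labels are written back onto the segment records.
    """
    x = polarity * trace.values
    prom = prominence_frac * float(np.ptp(x)) if x.size else 0.0
    mc_list: list[int] = []
    ao_list: list[int] = []
    for seg in segments:
        interior = x[seg.start_idx + 1:seg.end_idx]
        idx, _ = find_peaks(interior, prominence=prom if prom > 0 else None)
        idx = idx + seg.start_idx + 1
        if idx.size < 2:
            seg.flagged = True
            seg.mc_idx = seg.ao_prev_idx = -1
            continue
        seg.ao_prev_idx = int(idx[0])
        seg.mc_idx = int(idx[-1])
        ao_list.append(seg.ao_prev_idx)
        mc_list.append(seg.mc_idx)
    return McAoResult(mc_idx=np.array(mc_list, dtype=int),
                      ao_idx=np.array(ao_list, dtype=int),
                      segments=segments)
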