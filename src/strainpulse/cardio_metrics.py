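"""Cardiovascular parameters and agreement statistics.

Heart rate comes from peak-to-peak intervals (PPI) of a chosen fiducial
(SPG systolic peak, APG peak, or SCG AO peak).  Heart-rate variability is the
time-domain RMSSD of the PPIs.  Two modalities are compared beat-wise after
nearest-neighbour pairing; the agreement report carries the standard columns
(AVG, MAE, ME, SD, RMSE) plus a normalized-RMSE accuracy

    ACC_HR = 100 · (AVG − RMSE) / AVG,

and HRV agreement uses the symmetric relative accuracy

    ACC_HRV = 100 · (1 − 2·|HRV₁ − HRV₂| / (HRV₁ + HRV₂)).

Pulse arrival time (PAT) is the interval from the SCG MC peak to the SPG
systolic peak of the same beat; pulse transit time (PTT) is the interval from
the AO peak to the systolic peak.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "HR_GATE_BPM",
    "HrSeries",
    "AgreementReport",
    "PatPttReport",
    "ppi_from_peaks",
    "hr_series",
    "rmssd",
    "match_beats",
    "hr_agreement",
    "compare_hr",
    "hrv_accuracy",
    "compute_pat_ptt",
]

log = logging.getLogger(__name__)

#: Physiological gate on beat-wise heart rate (BPM, open interval).
HR_GATE_BPM = (20.0, 300.0)


@dataclass
class HrSeries:
    """Beat-aligned heart-rate values with their interval end times."""

    values_bpm: np.ndarray
    times_s: np.ndarray
    modality: str = "SPG"
    n_gated: int = 0

    def __post_init__(self) -> None:
        self.values_bpm = np.asarray(self.values_bpm, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values_bpm.size != self.times_s.size:
            raise ConfigurationError("HR values and times must align")


@dataclass
class AgreementReport:
    """Beat-wise HR agreement between a test and a reference modality."""

    avg_bpm: float
    mae_bpm: float
    me_bpm: float
    sd_bpm: float
    rmse_bpm: float
    acc_pct: float
    n_beats: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatPttReport:
    """Per-recording PAT/PTT summary (means ± SD over valid beats)."""

    pat_mean_ms: float
    pat_sd_ms: float
    ptt_mean_ms: float
    ptt_sd_ms: float
    n_beats: int
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def ppi_from_peaks(peak_times_s: np.ndarray) -> np.ndarray:
    """Successive peak-to-peak intervals in ms (length n−1)."""
    t = np.asarray(peak_times_s, dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise DomainError("peak times must be strictly increasing")
    return np.diff(t) * 1000.0


def hr_series(ppi_ms: np.ndarray, times_s: np.ndarray | None = None,
              modality: str = "SPG") -> HrSeries:
    """Beat-wise HR = 60000/PPI, dropping values outside the physiological gate."""
    ppi = np.asarray(ppi_ms, dtype=float)
    if ppi.size == 0:
        return HrSeries(np.empty(0), np.empty(0), modality)
    hr = 60_000.0 / ppi
    keep = (hr > HR_GATE_BPM[0]) & (hr < HR_GATE_BPM[1])
    n_gated = int((~keep).sum())
    if n_gated:
        log.warning("%s: dropped %d beat(s) outside the %s BPM gate",
                    modality, n_gated, HR_GATE_BPM)
    t = np.asarray(times_s, dtype=float) if times_s is not None \
        else np.cumsum(ppi) / 1000.0
    return HrSeries(hr[keep], t[keep], modality, n_gated=n_gated)


def rmssd(ppi_ms: np.ndarray) -> float:
    """Root mean square of successive differences of the intervals, in ms."""
    ppi = np.asarray(ppi_ms, dtype=float)
    if ppi.size < 2:
        raise DomainError("RMSSD requires at least two intervals")
    return float(np.sqrt(np.mean(np.diff(ppi) ** 2)))


def match_beats(test_times_s: np.ndarray, ref_times_s: np.ndarray,
                window_s: float | None = None) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour beat pairing within ±window.

    Each beat is used at most once; pairs are accepted in order of increasing
    absolute lag.  Default window: half the median reference inter-beat
    interval.  Returns (test index, ref index) pairs sorted by test index.
    """
    tt = np.asarray(test_times_s, dtype=float)
    rt = np.asarray(ref_times_s, dtype=float)
    if tt.size == 0 or rt.size == 0:
        return []
    if window_s is None:
        window_s = 0.5 * float(np.median(np.diff(rt))) if rt.size > 1 else 0.5
    cand = [(abs(t - r), i, j) for i, t in enumerate(tt) for j, r in enumerate(rt)
            if abs(t - r) <= window_s]
    cand.sort()
    used_t: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i not in used_t and j not in used_r:
            pairs.append((i, j))
            used_t.add(i)
            used_r.add(j)
    return sorted(pairs)


def hr_agreement(test: HrSeries, ref: HrSeries,
                 pairs: list[tuple[int, int]]) -> AgreementReport:
    """Agreement report over matched beat pairs; AVG is the reference-mean HR."""
    if len(pairs) < 2:
        raise DomainError("need at least two matched beats")
    ti = np.array([i for i, _ in pairs])
    rj = np.array([j for _, j in pairs])
    e = test.values_bpm[ti] - ref.values_bpm[rj]
    avg = float(np.mean(ref.values_bpm[rj]))
    if avg <= 0:
        raise DomainError("non-positive reference average HR")
    rmse = float(np.sqrt(np.mean(e**2)))
    return AgreementReport(
        avg_bpm=avg,
        mae_bpm=float(np.mean(np.abs(e))),
        me_bpm=float(np.mean(e)),
        sd_bpm=float(np.std(e, ddof=1)),
        rmse_bpm=rmse,
        acc_pct=100.0 * (avg - rmse) / avg,
        n_beats=len(pairs),
    )


def compare_hr(test_times_s: np.ndarray, ref_times_s: np.ndarray,
               window_s: float | None = None,
               modalities: tuple[str, str] = ("SPG", "SCG")) -> AgreementReport:
    """Convenience chain: pair beats, derive interval HR on both sides, report.

    HR is computed from intervals between successive *matched* beats on each
    side, so a missed beat removes the same interval from both series; beats
    outside the HR gate on either side are dropped pairwise.
    """
    pairs = match_beats(test_times_s, ref_times_s, window_s)
    if len(pairs) < 3:
        raise DomainError("need at least three matched beats for interval HR")
    tt = np.asarray(test_times_s, dtype=float)[[i for i, _ in pairs]]
    rt = np.asarray(ref_times_s, dtype=float)[[j for _, j in pairs]]
    test_hr = 60_000.0 / ppi_from_peaks(tt)
    ref_hr = 60_000.0 / ppi_from_peaks(rt)
    lo, hi = HR_GATE_BPM
    keep = (test_hr > lo) & (test_hr < hi) & (ref_hr > lo) & (ref_hr < hi)
    ts = HrSeries(test_hr[keep], tt[1:][keep], modalities[0])
    rs = HrSeries(ref_hr[keep], rt[1:][keep], modalities[1])
    return hr_agreement(ts, rs, [(k, k) for k in range(ts.values_bpm.size)])


def hrv_accuracy(hrv1_ms: float, hrv2_ms: float) -> float:
    """Symmetric relative HRV agreement in percent; 100 iff the HRVs are equal."""
    denom = hrv1_ms + hrv2_ms
    if denom == 0:
        raise DomainError("HRV accuracy undefined when both HRVs are zero")
    return 100.0 * (1.0 - 2.0 * abs(hrv1_ms - hrv2_ms) / denom)


def compute_pat_ptt(systolic_times_s: np.ndarray, mc_times_s: np.ndarray,
                    ao_times_s: np.ndarray,
                    max_interval_ms: float = 600.0) -> PatPttReport:
    """Per-beat PAT (systolic − MC) and PTT (systolic − AO), summarized.

    For each systolic peak the latest preceding MC and AO within
    ``max_interval_ms`` are taken as the same beat's valve events; beats where
    either interval is non-positive or exceeds the window are excluded and
    counted.
    """
    sys_t = np.asarray(systolic_times_s, dtype=float)
    mc = np.sort(np.asarray(mc_times_s, dtype=float))
    ao = np.sort(np.asarray(ao_times_s, dtype=float))
    pats, ptts = [], []
    n_excluded = 0
    for s in sys_t:
        pat = ptt = None
        i = np.searchsorted(mc, s) - 1
        if i >= 0:
            pat = (s - mc[i]) * 1000.0
        j = np.searchsorted(ao, s) - 1
        if j >= 0:
            ptt = (s - ao[j]) * 1000.0
        ok = (pat is not None and 0.0 < pat <= max_interval_ms and
              ptt is not None and 0.0 < ptt <= max_interval_ms)
        if ok:
            pats.append(pat)
            ptts.append(ptt)
        else:
            n_excluded += 1
    if not pats:
        raise DomainError("no valid beats for PAT/PTT")
    pats_a, ptts_a = np.array(pats), np.array(ptts)
    sd = lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return PatPttReport(
        pat_mean_ms=float(np.mean(pats_a)), pat_sd_ms=sd(pats_a),
        ptt_mean_ms=float(np.mean(ptts_a)), ptt_sd_ms=sd(ptts_a),
        n_beats=int(pats_a.size), n_excluded=n_excluded,
    )
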