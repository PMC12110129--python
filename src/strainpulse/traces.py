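"""Uniformly sampled single-channel time series and their CSV representation.

A :class:`SignalTrace` is the package's in-memory container for one channel of
sensor data: raw ADC counts, capacitance in attofarad (aF), strain in
microstrain (µε), or a dimensionless normalized waveform.  On disk a trace is
a two-column CSV (``time_s,value``) with a JSON sidecar
(``<name>.meta.json``) carrying the units and sampling rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SignalTrace", "read_trace", "write_trace"]


@dataclass
class SignalTrace:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    values
        Sample values (converted to a float64 array).
    fs_hz
        Sampling rate in Hz; must be positive.
    units
        One of ``counts``, ``aF``, ``ue`` (microstrain), ``normalized`` or
        ``au`` (arbitrary units). Not enforced — informational metadata.
    t0_s
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs_hz: float
    units: str = "au"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigurationError("trace values must be one-dimensional")
        if not self.fs_hz > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs_hz}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SignalTrace":
        """A copy of the trace carrying new sample values (same time base)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".meta.json")


def write_trace(trace: SignalTrace, csv_path: str | Path) -> Path:
    """Write a trace as ``time_s,value`` CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.values})
    df.to_csv(csv_path, index=False)
    meta = {"units": trace.units, "sampling_rate_hz": trace.fs_hz, "t0_s": trace.t0_s}
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trace(csv_path: str | Path) -> SignalTrace:
    """Read a trace written by :func:`write_trace`.

    If the sidecar is missing, the sampling rate is inferred from the time
    column (which must be uniform to 1 ppm).
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ConfigurationError(f"{csv_path} lacks required columns time_s,value")
    sidecar = _sidecar_path(csv_path)
    t = df["time_s"].to_numpy(dtype=float)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["sampling_rate_hz"])
        units = str(meta.get("units", "au"))
        t0 = float(meta.get("t0_s", t[0] if t.size else 0.0))
    else:
        if t.size < 2:
            raise ConfigurationError(f"{csv_path}: cannot infer sampling rate from < 2 samples")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise ConfigurationError(f"{csv_path}: non-uniform time column and no sidecar")
        fs = 1.0 / dt.mean()
        units, t0 = "au", t[0]
    return SignalTrace(df["value"].to_numpy(dtype=float), fs_hz=fs, units=units, t0_s=t0)
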