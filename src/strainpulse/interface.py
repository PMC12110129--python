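"""Experiment configuration, scenario presets and file-level run drivers.

Scenarios mirror the measurement protocols: ``fingertip`` and ``wrist`` pulse
recordings with respiratory baseline drift, ``phone`` with grip-pressure
artifacts, and the two blood-pressure conditions ``bp_normal`` /
``bp_elevated`` whose PAT/PTT presets are the reported normal and
post-exercise means (222.8/152.4 ms and 187.9/143.4 ms).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import cardio_metrics as cm
from .errors import ConfigurationError
from .pipeline import analyze_recording
from .sensor_model import SensorParams
from .synthetic_data import (GroundTruth, RecordingConfig, make_recording,
                             write_recording)
from .traces import read_trace

__all__ = ["ExperimentConfig", "SCENARIO_PRESETS", "run_simulate", "run_process",
           "run_report"]

log = logging.getLogger(__name__)

SCENARIO_PRESETS: dict[str, dict] = {
    "fingertip": {"drift_mode": "respiratory", "drift_amplitude_ue": 10.0},
    "wrist": {"drift_mode": "respiratory", "drift_amplitude_ue": 15.0},
    "phone": {"drift_mode": "grip", "drift_amplitude_ue": 60.0},
    "bp_normal": {"pat_ms": 222.8, "ptt_ms": 152.4,
                  "drift_mode": "respiratory", "drift_amplitude_ue": 10.0},
    "bp_elevated": {"pat_ms": 187.9, "ptt_ms": 143.4,
                    "drift_mode": "respiratory", "drift_amplitude_ue": 10.0},
}


class ExperimentConfig(BaseModel):
    """Validated configuration for one simulated experiment run."""

    scenario: Literal["fingertip", "wrist", "phone", "bp_normal", "bp_elevated"] = "fingertip"
    duration_s: float = Field(default=30.0, gt=0)
    hr_mean_bpm: float = Field(default=70.0, gt=0)
    rmssd_ms: float = Field(default=30.0, ge=0)
    pat_ms: float = Field(default=222.8, gt=0)
    ptt_ms: float = Field(default=152.4, gt=0)
    sampling_rate_hz: float = Field(default=25_000.0, gt=0)
    peak_strain_ue: float = Field(default=50.0, gt=0)
    noise_rms_aF: float = Field(default=400.0, ge=0)
    adc_bits: int = Field(default=14, ge=1)
    scg_noise_rms: float = Field(default=0.02, ge=0)
    drift_mode: Literal["respiratory", "grip"] | None = "respiratory"
    drift_amplitude_ue: float = Field(default=10.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_timing(self) -> "ExperimentConfig":
        if self.pat_ms <= self.ptt_ms:
            raise ValueError("pat_ms must exceed ptt_ms")
        return self

    @classmethod
    def from_scenario(cls, scenario: str, **overrides) -> "ExperimentConfig":
        """Build a config from a scenario preset; explicit overrides win."""
        if scenario not in SCENARIO_PRESETS:
            raise ConfigurationError(f"unknown scenario {scenario!r}")
        merged = {"scenario": scenario, **SCENARIO_PRESETS[scenario], **overrides}
        return cls(**merged)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        data = json.loads(Path(path).read_text())
        scenario = data.pop("scenario", "fingertip")
        return cls.from_scenario(scenario, **data)

    def to_recording_config(self) -> RecordingConfig:
        return RecordingConfig(
            duration_s=self.duration_s, fs_hz=self.sampling_rate_hz,
            hr_mean_bpm=self.hr_mean_bpm, rmssd_ms=self.rmssd_ms,
            pat_ms=self.pat_ms, ptt_ms=self.ptt_ms,
            peak_strain_ue=self.peak_strain_ue, noise_rms_aF=self.noise_rms_aF,
            adc_bits=self.adc_bits, scg_noise_rms=self.scg_noise_rms,
            drift_mode=self.drift_mode, drift_amplitude_ue=self.drift_amplitude_ue,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


def run_simulate(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a recording and write SPG/SCG CSVs plus the ground-truth JSON."""
    rec = make_recording(config.to_recording_config(), rng_seed=config.seed)
    paths = write_recording(rec, out_dir)
    snapshot = Path(out_dir) / "experiment_config.json"
    snapshot.write_text(json.dumps(
        {"config": config.model_dump(), "config_hash": config.config_hash()}, indent=1))
    paths["config"] = snapshot
    log.info("simulated %s scenario: %d beats, seed %d",
             config.scenario, rec.ground_truth.beat_times_s.size, config.seed)
    return paths


def _annotations_frame(analysis) -> pd.DataFrame:
    rows = []
    channels = [
        ("onset", analysis.spg.onset_times_s),
        ("systolic", analysis.spg.systolic_times_s),
        ("apg_peak", analysis.spg.apg_peak_times_s),
        ("MC", analysis.scg.mc_times_s),
        ("IM", analysis.scg.im_times_s),
        ("AO", analysis.scg.ao_times_s),
    ]
    for name, times in channels:
        for k, t in enumerate(np.asarray(times)):
            rows.append({"beat_index": k, "fiducial_name": name, "time_s": float(t)})
    return pd.DataFrame(rows, columns=["beat_index", "fiducial_name", "time_s"])


def _recovery_report(analysis, truth: GroundTruth) -> dict:
    """Detected-vs-true fiducial timing audit (medians of |error| in ms)."""
    out = {}
    pairs = [
        ("systolic", analysis.spg.systolic_times_s, truth.spg["systolic"]),
        ("onset", analysis.spg.onset_times_s, truth.spg["onset"]),
        ("max_slope", analysis.spg.apg_peak_times_s, truth.spg["max_slope"]),
        ("mc", analysis.scg.mc_times_s, truth.scg["mc"]),
        ("ao", analysis.scg.ao_times_s, truth.scg["ao"]),
    ]
    for name, detected, true in pairs:
        true = true[~np.isnan(true)]
        matches = cm.match_beats(np.asarray(detected), true)
        if not matches:
            out[name] = {"n_matched": 0}
            continue
        err = np.array([detected[i] - true[j] for i, j in matches]) * 1000.0
        out[name] = {
            "n_matched": len(matches),
            "n_true": int(true.size),
            "median_abs_error_ms": float(np.median(np.abs(err))),
            "mean_error_ms": float(np.mean(err)),
        }
    return out


def run_process(spg_csv: str | Path, scg_csv: str | Path,
                out_dir: str | Path, params: SensorParams | None = None,
                truth_json: str | Path | None = None,
                min_ibi_s: float = 0.3) -> dict:
    """Process a recorded pair of CSV traces and write annotations + reports.

    Returns the summary dict that is also written to ``report.json``.  When a
    ground-truth JSON is supplied, an additional recovery report compares the
    detected fiducials with the true ones.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spg_trace = read_trace(spg_csv)
    scg_trace = read_trace(scg_csv)
    analysis = analyze_recording(spg_trace, scg_trace, min_ibi_s=min_ibi_s)

    _annotations_frame(analysis).to_csv(out_dir / "annotations.csv", index=False)
    summary = {
        "n_systolic": int(analysis.spg.systolic_idx.size),
        "n_ao": int(analysis.scg.ao_idx.size),
        "n_flagged_scg_beats": int(analysis.scg.n_flagged),
        "hr_agreement": {k: r.as_dict() for k, r in analysis.hr_reports.items()},
        "hrv_rmssd_ms": analysis.hrv_rmssd_ms,
        "hrv_accuracy_pct": analysis.hrv_accuracy_pct,
        "pat_ptt": analysis.pat_ptt.as_dict() if analysis.pat_ptt else None,
    }
    if truth_json is not None:
        payload = json.loads(Path(truth_json).read_text())
        truth = GroundTruth.from_json_dict(payload["ground_truth"])
        summary["recovery"] = _recovery_report(analysis, truth)
    (out_dir / "report.json").write_text(json.dumps(summary, indent=1))
    log.info("processed recording: %d systolic peaks, %d AO peaks, %d flagged SCG beats",
             summary["n_systolic"], summary["n_ao"], summary["n_flagged_scg_beats"])
    return summary


_REPORT_COLUMNS = ["label", "pair", "avg_bpm", "mae_bpm", "me_bpm", "sd_bpm",
                   "rmse_bpm", "acc_pct", "hrv_acc_pct", "pat_mean_ms", "pat_sd_ms",
                   "ptt_mean_ms", "ptt_sd_ms", "n_beats"]


def run_report(report_jsons: list[str | Path], out_csv: str | Path) -> pd.DataFrame:
    """Aggregate per-recording report JSONs into one summary table.

    One row per (recording, modality pair) with the HR agreement columns,
    the matching HRV accuracy, and the recording's PAT/PTT summary.
    """
    rows = []
    for path in report_jsons:
        path = Path(path)
        data = json.loads(path.read_text())
        if "hr_agreement" not in data:
            raise ConfigurationError(f"{path} is not a recording report")
        label = path.parent.name or path.stem
        patptt = data.get("pat_ptt") or {}
        for pair, rep in data["hr_agreement"].items():
            rows.append({
                "label": label, "pair": pair,
                "avg_bpm": rep["avg_bpm"], "mae_bpm": rep["mae_bpm"],
                "me_bpm": rep["me_bpm"], "sd_bpm": rep["sd_bpm"],
                "rmse_bpm": rep["rmse_bpm"], "acc_pct": rep["acc_pct"],
                "hrv_acc_pct": data.get("hrv_accuracy_pct", {}).get(pair),
                "pat_mean_ms": patptt.get("pat_mean_ms"),
                "pat_sd_ms": patptt.get("pat_sd_ms"),
                "ptt_mean_ms": patptt.get("ptt_mean_ms"),
                "ptt_sd_ms": patptt.get("ptt_sd_ms"),
                "n_beats": rep["n_beats"],
            })
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(out_csv, index=False)
    return df
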