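#!/usr/bin/env python
"""Figures: processed SPG/SCG waveforms with detected fiducials (to scratch/).

Plots a few seconds of the normalized SPG trace with onset/systolic/APG-peak
markers and of the normalized SCG trace with MC/IM/AO markers, plus the
per-beat PAT/PTT series.  PNG output goes under scratch/figures/.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from strainpulse.interface import ExperimentConfig
from strainpulse.pipeline import analyze_recording
from strainpulse.synthetic_data import make_recording

FIG = Path(__file__).resolve().parent.parent / "scratch" / "figures"
FIG.mkdir(parents=True, exist_ok=True)

cfg = ExperimentConfig.from_scenario("bp_normal", seed=1)
rec = make_recording(cfg.to_recording_config(), rng_seed=cfg.seed)
ana = analyze_recording(rec.spg_counts, rec.scg_counts)

t0, t1 = 5.0, 10.0
fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
for ax, chan, marks in (
        (axes[0], ana.spg.normalized,
         [("onset", ana.spg.onset_times_s, "v"),
          ("systolic", ana.spg.systolic_times_s, "^"),
          ("max slope", ana.spg.apg_peak_times_s, "x")]),
        (axes[1], ana.scg.normalized,
         [("MC", ana.scg.mc_times_s, "o"),
          ("IM", ana.scg.im_times_s, "s"),
          ("AO", ana.scg.ao_times_s, "d")])):
    t = chan.times()
    win = (t >= t0) & (t <= t1)
    ax.plot(t[win], chan.values[win], lw=0.8, color="0.3")
    for label, times, marker in marks:
        sel = times[(times >= t0) & (times <= t1)]
        idx = (sel * chan.fs_hz).astype(int)
        ax.plot(sel, chan.values[idx], marker, ms=5, label=label, ls="none")
    ax.legend(loc="upper right", fontsize=8)
axes[0].set_ylabel("SPG (norm.)")
axes[1].set_ylabel("SCG (norm.)")
axes[1].set_xlabel("time (s)")
fig.tight_layout()
fig.savefig(FIG / "waveforms_fiducials.png", dpi=150)

rep = ana.pat_ptt
print(f"figures in {FIG}; PAT {rep.pat_mean_ms:.1f} ± {rep.pat_sd_ms:.1f} ms, "
      f"PTT {rep.ptt_mean_ms:.1f} ± {rep.ptt_sd_ms:.1f} ms over {rep.n_beats} beats")
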