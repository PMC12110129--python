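#!/usr/bin/env python
"""Sensor calibration arithmetic: gauge factors, resolution, linearity.

Evaluates the transduction model at the characterized operating point — the
die-level FEM sensitivity (2.34 fF/µε), the system-level characterized
sensitivity (316 aF/µε over four 2.2 pF variable capacitors), the ~400 aF
capacitance noise and the 25 kHz sampling — and tabulates what they imply:
gauge factors, noise-equivalent strain resolution, timing resolution, and the
size of the second-order term the differential pair cancels.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from strainpulse.sensor_model import (CapacitorGeometry, SensorParams,
                                      differential_capacitance, gauge_factor,
                                      noise_to_resolution)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = SensorParams()
rows = [
    {"quantity": "die_gauge_factor", "value": gauge_factor(2340.0, 8.8e6),
     "units": "", "inputs": "S=2.34 fF/ue, C0=8.8 pF"},
    {"quantity": "system_gauge_factor", "value": gauge_factor(316.0, 4 * 2.2e6),
     "units": "", "inputs": "S=316 aF/ue, C0=4x2.2 pF"},
    {"quantity": "strain_resolution", "value": noise_to_resolution(400.0, 316.0),
     "units": "ue", "inputs": "noise 400 aF RMS"},
    {"quantity": "timing_resolution", "value": 1e6 / params.sampling_rate_hz,
     "units": "us", "inputs": "fs=25 kHz"},
    {"quantity": "adc_lsb", "value": params.lsb_aF,
     "units": "aF", "inputs": "14-bit over +/- full scale"},
]

# residual nonlinearity of the differential pair across a +/-10% gap swing
geom = CapacitorGeometry.from_nominal_capacitance(2.2e-12, 200e-9)
ratios = np.linspace(-0.1, 0.1, 201)[1:-1]
ratios = ratios[ratios != 0]
dev = [abs(differential_capacitance(r * geom.nominal_gap_m, geom, "exact")
           - differential_capacitance(r * geom.nominal_gap_m, geom, "linearized"))
       / abs(differential_capacitance(r * geom.nominal_gap_m, geom, "linearized"))
       for r in ratios]
rows.append({"quantity": "max_linearization_deviation_10pct_gap",
             "value": max(dev), "units": "fraction", "inputs": "|dd| <= 0.1 d0"})

df = pd.DataFrame(rows)
df.to_csv(OUT / "sensor_characterization.csv", index=False)
print(df.to_string(index=False))
print("\nThe die-level gauge factor evaluates to ~266 and the system-level one "
      "to ~36; the 400 aF noise floor maps to a ~1.27 ue strain resolution, and "
      "the residual quadratic error of the differential pair stays below "
      f"{max(dev):.2%} over a +/-10% gap swing.")
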