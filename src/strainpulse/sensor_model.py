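"""Physics of the hermetically sealed capacitive MEMS strain sensor.

The sensor is a differential pair of parallel-plate variable capacitors with a
nano-scale nominal gap.  An input strain deflects the anchors relative to the
suspended plate, changing the gaps of the C+ and C− capacitors in opposite
directions.  The differential output

    ΔC = ε₀A/(d₀ − δd) − ε₀A/(d₀ + δd) = 2ε₀A δd / d₀² + O(δd³)

cancels the even-order nonlinearity, so the sensor responds linearly over a
wide strain range.  This module implements the transduction and calibration
relations (differential capacitance, beam strain, sensitivity, gauge factor,
noise-equivalent resolution) plus a forward simulator that turns a strain
waveform into the noisy, quantized counts an ASIC with an N-bit ADC would
report.

Unit conventions
----------------
Capacitance is carried in attofarad (aF) and strain in microstrain (µε)
throughout the public API — the natural reporting units for this class of
sensor — and converted to SI only inside the physics formulas, which take SI
metres/farads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError
from .traces import SignalTrace

__all__ = [
    "EPSILON_0",
    "CapacitorGeometry",
    "BeamModel",
    "CantileverSetup",
    "SensorParams",
    "differential_capacitance",
    "prismatic_beam_strain",
    "cantilever_surface_strain",
    "strain_sensitivity",
    "gauge_factor",
    "noise_to_resolution",
    "transduce",
    "counts_to_capacitance",
    "counts_to_strain",
]

#: Vacuum permittivity (F/m); the air gap's permittivity to within 0.06%.
EPSILON_0 = 8.8541878128e-12


@dataclass(frozen=True)
class CapacitorGeometry:
    """Parallel-plate geometry of one variable capacitor.

    Attributes
    ----------
    plate_area_m2
        Overlap area A of the plates (m²).
    nominal_gap_m
        Gap d₀ at zero input strain (m).
    epsilon0
        Permittivity of the gap medium (F/m); defaults to air/vacuum.
    """

    plate_area_m2: float
    nominal_gap_m: float
    epsilon0: float = EPSILON_0

    def __post_init__(self) -> None:
        if not self.plate_area_m2 > 0:
            raise DomainError("plate area must be positive")
        if not self.nominal_gap_m > 0:
            raise DomainError("nominal gap must be positive")
        if not self.epsilon0 > 0:
            raise DomainError("permittivity must be positive")

    @property
    def nominal_capacitance_F(self) -> float:
        """Single-capacitor nominal capacitance ε₀A/d₀ (F)."""
        return self.epsilon0 * self.plate_area_m2 / self.nominal_gap_m

    @classmethod
    def from_nominal_capacitance(cls, capacitance_F: float, nominal_gap_m: float,
                                 epsilon0: float = EPSILON_0) -> "CapacitorGeometry":
        """Geometry with the plate area chosen to give the stated nominal capacitance."""
        if not capacitance_F > 0:
            raise DomainError("nominal capacitance must be positive")
        area = capacitance_F * nominal_gap_m / epsilon0
        return cls(plate_area_m2=area, nominal_gap_m=nominal_gap_m, epsilon0=epsilon0)


@dataclass(frozen=True)
class BeamModel:
    """Prismatic-beam idealization of the sensor die under axial edge displacement."""

    beam_length_m: float
    beam_thickness_m: float
    edge_displacement_m: float = 0.0

    def __post_init__(self) -> None:
        if not self.beam_length_m > 0:
            raise DomainError("beam length must be positive")
        if not self.beam_thickness_m > 0:
            raise DomainError("beam thickness must be positive")


@dataclass(frozen=True)
class CantileverSetup:
    """Cantilever calibration rig: tip-deflected beam with the sensor bonded on top.

    ``sensor_position_m`` is the distance d of the sensor from the FIXED end of
    the cantilever, so surface strain is maximal at d = 0 and zero at d = Lc.
    """

    length_m: float
    thickness_m: float
    tip_displacement_m: float
    sensor_position_m: float = 0.0

    def __post_init__(self) -> None:
        if not self.length_m > 0:
            raise DomainError("cantilever length must be positive")
        if not self.thickness_m > 0:
            raise DomainError("cantilever thickness must be positive")
        if not 0.0 <= self.sensor_position_m <= self.length_m:
            raise DomainError(
                f"sensor position {self.sensor_position_m} outside [0, {self.length_m}]")


@dataclass(frozen=True)
class SensorParams:
    """Transduction constants of the complete strain sensing system.

    Defaults are the characterized values of the sensing system: sensitivity
    316 aF/µε, total nominal capacitance 8.8 pF (four 2.2 pF variable
    capacitors), ±700 µε linear range, ~400 aF RMS capacitance noise, a 14-bit
    ADC and 25 kHz sampling.

    ``adc_full_scale_aF`` is the one-sided full scale: the ADC maps
    [−FS, +FS] onto 2^bits uniform codes.  When omitted it defaults to
    S·linear_range + 6·noise_rms so the linear range plus noise excursions fit
    inside the code space.
    """

    sensitivity_aF_per_ue: float = 316.0
    c0_aF: float = 8.8e6
    linear_range_ue: float = 700.0
    noise_rms_aF: float = 400.0
    adc_bits: int = 14
    adc_full_scale_aF: float | None = None
    sampling_rate_hz: float = 25_000.0

    def __post_init__(self) -> None:
        if not self.sensitivity_aF_per_ue > 0:
            raise DomainError("sensitivity must be positive")
        if not self.c0_aF > 0:
            raise DomainError("nominal capacitance must be positive")
        if not self.linear_range_ue > 0:
            raise DomainError("linear range must be positive")
        if self.noise_rms_aF < 0:
            raise DomainError("noise RMS must be non-negative")
        if int(self.adc_bits) < 1:
            raise DomainError("ADC needs at least 1 bit")
        if not self.sampling_rate_hz > 0:
            raise DomainError("sampling rate must be positive")
        if self.adc_full_scale_aF is not None and not self.adc_full_scale_aF > 0:
            raise DomainError("ADC full scale must be positive")

    @property
    def full_scale_aF(self) -> float:
        if self.adc_full_scale_aF is not None:
            return self.adc_full_scale_aF
        return self.sensitivity_aF_per_ue * self.linear_range_ue + 6.0 * self.noise_rms_aF

    @property
    def n_codes(self) -> int:
        return 2 ** int(self.adc_bits)

    @property
    def lsb_aF(self) -> float:
        """Code width: full span 2·FS divided over 2^bits codes."""
        return 2.0 * self.full_scale_aF / self.n_codes

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sensitivity_aF_per_ue": self.sensitivity_aF_per_ue,
            "c0_aF": self.c0_aF,
            "linear_range_ue": self.linear_range_ue,
            "noise_rms_aF": self.noise_rms_aF,
            "adc_bits": int(self.adc_bits),
            "adc_full_scale_aF": self.adc_full_scale_aF,
            "sampling_rate_hz": self.sampling_rate_hz,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SensorParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(**data)


def differential_capacitance(delta_d_m: float | np.ndarray,
                             geometry: CapacitorGeometry,
                             mode: str = "exact") -> float | np.ndarray:
    """Differential output ΔC (F) of the C+/C− pair for a gap change δd.

    ``mode="exact"`` evaluates ε₀A/(d₀−δd) − ε₀A/(d₀+δd); ``mode="linearized"``
    keeps only the first-order term 2ε₀A δd/d₀².  Both are odd in δd.
    """
    delta_d = np.asarray(delta_d_m, dtype=float)
    d0 = geometry.nominal_gap_m
    if np.any(np.abs(delta_d) >= d0):
        raise DomainError("|delta_d| >= nominal gap: plate contact")
    ea = geometry.epsilon0 * geometry.plate_area_m2
    if mode == "exact":
        out = ea / (d0 - delta_d) - ea / (d0 + delta_d)
    elif mode == "linearized":
        out = 2.0 * ea * delta_d / d0**2
    else:
        raise ConfigurationError(f"unknown mode {mode!r}; use 'exact' or 'linearized'")
    return out if out.ndim else float(out)


def prismatic_beam_strain(beam: BeamModel) -> float:
    """Axial strain ε = δL/Lb of the prismatic beam model, in µε."""
    return beam.edge_displacement_m / beam.beam_length_m * 1e6


def cantilever_surface_strain(setup: CantileverSetup) -> float:
    """Surface strain at position d on a tip-deflected cantilever, in µε.

    ε = 3 tc δy (Lc − d) / (2 Lc³), with d measured from the fixed end.  The
    strain is largest at the fixed end and vanishes at the free end where the
    bending moment is zero.
    """
    lc = setup.length_m
    eps = 3.0 * setup.thickness_m * setup.tip_displacement_m * (lc - setup.sensor_position_m) \
        / (2.0 * lc**3)
    return eps * 1e6


def strain_sensitivity(delta_c_aF: float, strain_ue: float) -> float:
    """Sensitivity S = ΔC/ε in aF/µε."""
    if strain_ue == 0:
        raise DomainError("sensitivity undefined at zero strain")
    return delta_c_aF / strain_ue


def gauge_factor(sensitivity_aF_per_ue: float, c0_aF: float) -> float:
    """Dimensionless gauge factor GF = ΔC/(ε C₀) = (S/C₀)·10⁶ for S per µε."""
    if not c0_aF > 0:
        raise DomainError("nominal capacitance must be positive")
    return sensitivity_aF_per_ue / c0_aF * 1e6


def noise_to_resolution(noise_rms_aF: float, sensitivity_aF_per_ue: float) -> float:
    """Noise-equivalent strain resolution in µε: capacitance noise over sensitivity."""
    if not sensitivity_aF_per_ue > 0:
        raise DomainError("sensitivity must be positive")
    return noise_rms_aF / sensitivity_aF_per_ue


def _quantize(cap_aF: np.ndarray, params: SensorParams) -> np.ndarray:
    """Map capacitance to integer ADC codes: [−FS, +FS] onto 2^bits uniform codes."""
    codes = np.rint((cap_aF + params.full_scale_aF) / params.lsb_aF)
    return np.clip(codes, 0, params.n_codes - 1)


def transduce(strain: SignalTrace, params: SensorParams,
              rng_seed: int | np.random.SeedSequence = 0) -> SignalTrace:
    """Forward-simulate the sensing system: strain (µε) → quantized ADC counts.

    The strain is clipped to the ± linear range (hard saturation), scaled by
    the sensitivity, perturbed by white Gaussian capacitance noise of RMS
    ``noise_rms_aF``, and quantized by the N-bit ADC.  Deterministic for a
    given ``rng_seed``.
    """
    if abs(strain.fs_hz - params.sampling_rate_hz) > 1e-6 * params.sampling_rate_hz:
        raise ConfigurationError(
            f"trace sampled at {strain.fs_hz} Hz but sensor runs at {params.sampling_rate_hz} Hz")
    clipped = np.clip(strain.values, -params.linear_range_ue, params.linear_range_ue)
    cap = params.sensitivity_aF_per_ue * clipped
    if params.noise_rms_aF > 0:
        rng = np.random.default_rng(rng_seed)
        cap = cap + rng.normal(0.0, params.noise_rms_aF, size=cap.size)
    counts = _quantize(cap, params)
    return strain.with_values(counts, units="counts")


def counts_to_capacitance(counts: SignalTrace, params: SensorParams) -> SignalTrace:
    """Invert the ADC mapping: codes back to capacitance (aF), mid-code convention."""
    cap = counts.values * params.lsb_aF - params.full_scale_aF
    return counts.with_values(cap, units="aF")


def counts_to_strain(counts: SignalTrace, params: SensorParams) -> SignalTrace:
    """De-transduce counts to strain in µε (exact inverse inside the linear range
    up to noise and quantization)."""
    cap = counts_to_capacitance(counts, params)
    return cap.with_values(cap.values / params.sensitivity_aF_per_ue, units="ue")
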