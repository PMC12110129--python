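"""Sensor transduction physics: capacitance, strain, calibration, forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainpulse.errors import ConfigurationError, DomainError
from strainpulse.sensor_model import (BeamModel, CantileverSetup, CapacitorGeometry,
                                      SensorParams, cantilever_surface_strain,
                                      counts_to_strain, differential_capacitance,
                                      gauge_factor, noise_to_resolution,
                                      prismatic_beam_strain, strain_sensitivity,
                                      transduce)
from strainpulse.traces import SignalTrace

# geometry of one 2.2 pF variable capacitor with the 200 nm nano-gap
GEOM = CapacitorGeometry.from_nominal_capacitance(2.2e-12, 200e-9)


class TestDifferentialCapacitance:
    def test_zero_gap_change_gives_zero_in_both_modes(self):
        assert differential_capacitance(0.0, GEOM, "exact") == 0.0
        assert differential_capacitance(0.0, GEOM, "linearized") == 0.0

    def test_linearized_value_for_one_nm_deflection(self):
        # 2 * C_single * (delta_d / d0) = 2 * 2.2 pF * (1/200) = 22 fF
        out = differential_capacitance(1e-9, GEOM, "linearized")
        assert out == pytest.approx(22e-15, rel=1e-12)

    def test_exact_exceeds_linearized_by_relative_gap_ratio_squared(self):
        dd = 0.1 * GEOM.nominal_gap_m
        exact = differential_capacitance(dd, GEOM, "exact")
        lin = differential_capacitance(dd, GEOM, "linearized")
        # exact/lin = 1/(1 - r^2), deviation ~= r^2 = 1%
        assert (exact - lin) / lin == pytest.approx(0.01, rel=0.02)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.29, 0.29))
    def test_odd_symmetry_and_linearization_bound(self, ratio):
        dd = ratio * GEOM.nominal_gap_m
        for mode in ("exact", "linearized"):
            pos = differential_capacitance(dd, GEOM, mode)
            neg = differential_capacitance(-dd, GEOM, mode)
            assert pos == -neg
        if abs(ratio) > 1e-3:  # smaller gaps: cancellation noise dominates the O(r^2) term
            exact = differential_capacitance(dd, GEOM, "exact")
            lin = differential_capacitance(dd, GEOM, "linearized")
            assert abs(exact - lin) / abs(lin) <= 2.0 * ratio**2 + 1e-12

    def test_plate_contact_raises(self):
        with pytest.raises(DomainError):
            differential_capacitance(GEOM.nominal_gap_m, GEOM)

    def test_unknown_mode_raises(self):
        with pytest.raises(ConfigurationError):
            differential_capacitance(1e-9, GEOM, "cubic")


class TestBeamAndCantileverStrain:
    @pytest.mark.parametrize("delta_l, expected_ue", [(0.0, 0.0), (3.3e-9, 1.0)])
    def test_prismatic_strain_is_displacement_over_length(self, delta_l, expected_ue):
        beam = BeamModel(beam_length_m=3.3e-3, beam_thickness_m=1e-3,
                         edge_displacement_m=delta_l)
        assert prismatic_beam_strain(beam) == pytest.approx(expected_ue)

    def test_prismatic_strain_is_linear_in_displacement(self):
        b1 = BeamModel(3.3e-3, 1e-3, 5e-9)
        b2 = BeamModel(3.3e-3, 1e-3, 10e-9)
        assert prismatic_beam_strain(b2) == pytest.approx(2 * prismatic_beam_strain(b1))

    def test_cantilever_strain_at_fixed_end(self):
        # 3 * 0.004 * 0.001 * 0.2 / (2 * 0.2^3) = 1.5e-4 = 150 ue
        setup = CantileverSetup(length_m=0.2, thickness_m=0.004,
                                tip_displacement_m=0.001, sensor_position_m=0.0)
        assert cantilever_surface_strain(setup) == pytest.approx(150.0)

    def test_cantilever_strain_vanishes_at_free_end_and_for_zero_deflection(self):
        free = CantileverSetup(0.2, 0.004, 0.001, sensor_position_m=0.2)
        assert cantilever_surface_strain(free) == 0.0
        still = CantileverSetup(0.2, 0.004, 0.0, sensor_position_m=0.0)
        assert cantilever_surface_strain(still) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.1, 5.0))
    def test_cantilever_strain_monotone_in_position_linear_in_deflection(self, frac, k):
        lc = 0.2
        base = CantileverSetup(lc, 0.004, 1e-3, sensor_position_m=frac * lc)
        nearer = CantileverSetup(lc, 0.004, 1e-3, sensor_position_m=0.5 * frac * lc)
        assert cantilever_surface_strain(nearer) >= cantilever_surface_strain(base)
        scaled = CantileverSetup(lc, 0.004, k * 1e-3, sensor_position_m=frac * lc)
        assert cantilever_surface_strain(scaled) == pytest.approx(
            k * cantilever_surface_strain(base), rel=1e-9)

    def test_position_outside_beam_raises(self):
        with pytest.raises(DomainError):
            CantileverSetup(0.2, 0.004, 0.001, sensor_position_m=0.3)


class TestCalibration:
    def test_sensitivity_definition_and_scale_invariance(self):
        assert strain_sensitivity(316.0, 1.0) == 316.0
        assert strain_sensitivity(2340.0, 1.0) == pytest.approx(2.34e3)  # 2.34 fF/ue
        assert strain_sensitivity(5 * 316.0, 5.0) == strain_sensitivity(316.0, 1.0)
        with pytest.raises(DomainError):
            strain_sensitivity(100.0, 0.0)

    def test_die_level_gauge_factor(self):
        # S = 2.34 fF/ue and C0 = 8.8 pF give GF ~ 266
        assert gauge_factor(2340.0, 8.8e6) == pytest.approx(265.9, abs=0.1)

    def test_system_gauge_factor(self):
        # S = 316 aF/ue over four 2.2 pF capacitors gives GF ~ 36
        assert gauge_factor(316.0, 4 * 2.2e6) == pytest.approx(35.9, abs=0.1)

    def test_zero_sensitivity_gives_zero_gauge_factor(self):
        assert gauge_factor(0.0, 8.8e6) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_gauge_factor_invariant_to_measurement_scale(self, k):
        s = strain_sensitivity(k * 316.0, k * 1.0)
        assert gauge_factor(s, 8.8e6) == pytest.approx(gauge_factor(316.0, 8.8e6))

    def test_noise_equivalent_resolution(self):
        assert noise_to_resolution(400.0, 316.0) == pytest.approx(1.266, abs=0.001)
        assert noise_to_resolution(0.0, 316.0) == 0.0
        assert noise_to_resolution(800.0, 316.0) == 2 * noise_to_resolution(400.0, 316.0)
        with pytest.raises(DomainError):
            noise_to_resolution(400.0, 0.0)


class TestTransduce:
    def _params(self, **kw):
        defaults = dict(noise_rms_aF=0.0, sampling_rate_hz=1000.0)
        defaults.update(kw)
        return SensorParams(**defaults)

    def test_zero_strain_zero_noise_gives_constant_midscale_code(self):
        params = self._params()
        trace = SignalTrace(np.zeros(100), fs_hz=1000.0, units="ue")
        out = transduce(trace, params, rng_seed=0)
        assert np.all(out.values == params.n_codes / 2)

    def test_noiseless_ramp_roundtrips_through_high_resolution_adc(self):
        params = self._params(adc_bits=20)
        ramp = np.linspace(-600, 600, 2000)
        out = transduce(SignalTrace(ramp, 1000.0, "ue"), params, rng_seed=0)
        back = counts_to_strain(out, params)
        assert np.max(np.abs(back.values - ramp)) < 1e-3

    def test_sinusoid_amplitude_preserved_within_one_lsb(self):
        params = self._params(adc_bits=14)
        t = np.arange(2000) / 1000.0
        strain = 78.0 * np.sin(2 * np.pi * 5 * t)
        out = transduce(SignalTrace(strain, 1000.0, "ue"), params, rng_seed=0)
        amp_counts = (out.values.max() - out.values.min()) / 2.0
        expected = 78.0 * params.sensitivity_aF_per_ue / params.lsb_aF
        assert abs(amp_counts - expected) <= 1.0

    def test_saturation_clips_outside_linear_range(self):
        params = self._params(adc_bits=20)
        big = np.array([2000.0, -2000.0])
        out = counts_to_strain(transduce(SignalTrace(big, 1000.0, "ue"), params, 0), params)
        assert out.values == pytest.approx([700.0, -700.0], abs=1e-2)

    def test_same_seed_is_deterministic_different_seed_is_not(self):
        params = self._params(noise_rms_aF=400.0)
        trace = SignalTrace(np.zeros(500), 1000.0, "ue")
        a = transduce(trace, params, rng_seed=5).values
        b = transduce(trace, params, rng_seed=5).values
        c = transduce(trace, params, rng_seed=6).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_sampling_rate_mismatch_raises(self):
        params = self._params(sampling_rate_hz=25000.0)
        with pytest.raises(ConfigurationError):
            transduce(SignalTrace(np.zeros(10), 1000.0, "ue"), params, 0)
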