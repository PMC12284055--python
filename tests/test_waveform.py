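"""Signal-chain unit and property tests: autoranging, quantization,
current control, demodulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eitpsoc as e
from eitpsoc.waveform import _adc_quantize

CFG = e.DDSConfig()

# full autoranging table: (lower V, upper V, R_fb kOhm, register at lower bound)
TABLE_ROWS = [
    (0.15000, 0.63750, 20.0, 60),
    (0.63750, 0.95625, 30.0, 170),
    (0.95625, 1.27500, 40.0, 191),
    (1.27500, 2.55000, 80.0, 127),
    (2.55000, 3.82500, 120.0, 170),
    (3.82500, 4.62500, 250.0, 122),
]


class TestFeedbackSelection:
    @pytest.mark.parametrize(
        "v,expected", [(0.5, 20.0), (1.0, 40.0), (4.0, 250.0), (0.15, 20.0)]
    )
    def test_selects_table_row(self, v, expected):
        assert e.select_feedback_resistor(v) == expected

    @pytest.mark.parametrize("v", [0.1, 4.625, 5.0, -1.0])
    def test_out_of_range_names_span(self, v):
        with pytest.raises(ValueError, match=r"0\.15.*4\.625"):
            e.select_feedback_resistor(v)

    def test_rows_autorange_consistently(self):
        # each row's lower bound selects that row's resistance
        for lower, _, r_fb, _ in TABLE_ROWS:
            assert e.select_feedback_resistor(lower) == r_fb


class TestQuantizePeriod:
    @pytest.mark.parametrize("lower,upper,r_fb,d_lower", TABLE_ROWS)
    def test_register_ceiling_matches_table(self, lower, upper, r_fb, d_lower):
        """Max register reproduces both printed columns of every table row."""
        at_lower = e.quantize_period(lower, r_fb, CFG)
        assert at_lower.registers_plus.max() == d_lower
        just_below_upper = np.nextafter(upper, 0.0)
        ceiling = e.quantize_period(just_below_upper, r_fb, CFG).registers_plus.max()
        expected = math.floor(CFG.register_max * upper / (CFG.idac_full_scale_ua * 1e-6 * r_fb * 1e3) + 1e-9)
        # the upper bound itself belongs to the next row; just below it the
        # ceiling is the printed upper register (255, or 148 in the last row)
        assert ceiling in (expected, expected - 1)

    def test_peak_sample_positive_branch_only(self):
        period = e.quantize_period(1.0, 40.0, CFG)
        assert period.registers_minus[0] == 0
        assert period.registers_plus[0] == 200

    def test_full_scale_at_row_one_upper_bound(self):
        assert e.quantize_period(0.6375, 20.0, CFG).registers_plus.max() == 255

    def test_last_row_ceiling(self):
        assert e.quantize_period(3.825, 250.0, CFG).registers_plus.max() == 122

    def test_low_amplitude_uses_quarter_of_range(self):
        """Below 0.16 V at 20 kOhm only registers 0..63 occur."""
        ceilings = [
            e.quantize_period(v, 20.0, CFG).registers_plus.max()
            for v in np.linspace(0.15, 0.16, 101)[:-1]
        ]
        assert max(ceilings) == 63

    def test_registers_disjoint_and_bounded(self):
        period = e.quantize_period(2.0, 80.0, CFG)
        assert np.all((period.registers_plus == 0) | (period.registers_minus == 0))
        assert period.registers_plus.max() <= 255
        assert not period.saturated

    def test_saturation_flagged_and_clipped(self):
        period = e.quantize_period(1.0, 20.0, CFG)  # scale 400 >> 255
        assert period.saturated
        assert period.registers_plus.max() == 255

    def test_load_voltage_matches_registers(self):
        period = e.quantize_period(0.98, 40.0, CFG)
        vl = 40e3 * (period.registers_plus - period.registers_minus) * 31.875e-6 / 255
        np.testing.assert_allclose(period.load_voltage_samples, vl)

    @given(st.floats(min_value=0.16, max_value=4.6), st.sampled_from(TABLE_ROWS))
    @settings(max_examples=50, deadline=None)
    def test_register_bounds_property(self, v, row):
        lower, upper, r_fb, _ = row
        if not lower <= v < upper:
            v = lower + (v % (upper - lower))
        period = e.quantize_period(v, r_fb, CFG)
        expected = math.floor(
            255 * v / (31.875e-6 * r_fb * 1e3) + 1e-9
        )
        assert period.registers_plus.max() == min(expected, 255)
        assert period.registers_plus.min() == 0


class TestIdacCurrent:
    @pytest.mark.parametrize("reg,ua", [(0, 0.0), (255, 31.875), (128, 16.0)])
    def test_linear_map(self, reg, ua):
        assert e.idac_current(reg, CFG) == pytest.approx(ua)

    @pytest.mark.parametrize("reg", [-1, 256, 2.5])
    def test_invalid_register(self, reg):
        with pytest.raises(ValueError):
            e.idac_current(reg, CFG)


class TestTiaOutput:
    def test_symmetric_cancellation(self):
        _, _, vl = e.tia_output(10.0, 10.0, 40.0, 1.0)
        assert vl == 0.0

    def test_hand_computed_output(self):
        va, vb, vl = e.tia_output(31.875, 0.0, 20.0, 0.7)
        assert vl == pytest.approx(-0.6375)
        assert va > 0 and vb > 0

    def test_reference_too_low_names_minimum(self):
        with pytest.raises(ValueError, match="0.6375"):
            e.tia_output(31.875, 0.0, 20.0, 0.5)


class TestAmplitudeControl:
    def test_fixed_point(self):
        s = e.ControlState(amplitude_v=1.0, desired_current_a=1e-3)
        s2 = e.update_amplitude(s, 1e-3)
        assert s2.amplitude_v == pytest.approx(1.0)
        assert s2.period_index == 1

    def test_proportional_law(self):
        s = e.ControlState(amplitude_v=1.0, desired_current_a=0.98e-3)
        assert e.update_amplitude(s, 1e-3).amplitude_v == pytest.approx(0.98)
        assert e.update_amplitude(s, 2 * 0.98e-3).amplitude_v == pytest.approx(0.5)

    def test_open_circuit_rejected(self):
        s = e.ControlState()
        with pytest.raises(ValueError, match="open circuit"):
            e.update_amplitude(s, 0.0)

    def test_clipping_flagged_at_span_edges(self):
        s = e.ControlState(amplitude_v=4.0, desired_current_a=1e-3)
        high = e.update_amplitude(s, 1e-4)  # wants 40 V
        assert high.clipped and high.amplitude_v < 4.625
        low = e.update_amplitude(s, 1.0)  # wants 4 mV
        assert low.clipped and low.amplitude_v == 0.15


class TestClosedLoop:
    def test_second_period_reaches_setpoint(self):
        circuit = e.LoadCircuit(load_resistance_ohm=1000.0)
        trace = e.simulate_closed_loop(0.98e-3, circuit, n_periods=4)
        assert abs(trace[1].current_true_a - 0.98e-3) <= 0.01e-3

    def test_steady_state_error_within_quantization(self):
        """After convergence the residual error stays within one ADC step
        on the shunt voltage plus one DAC register step."""
        circuit = e.LoadCircuit(load_resistance_ohm=1000.0)
        trace = e.simulate_closed_loop(0.98e-3, circuit, n_periods=8)
        adc_step_a = (2 * circuit.adc_range_v / 2**circuit.adc_bits) / circuit.shunt_resistance_ohm
        dac_step_a = trace[-1].amplitude_v / 200 / 1100  # ~1 register LSB
        for rec in trace[1:]:
            assert abs(rec.current_true_a - 0.98e-3) <= adc_step_a + dac_step_a

    def test_load_step_reconverges_in_one_period(self):
        circuit = e.LoadCircuit(load_resistance_ohm=1000.0)
        schedule = [1000.0, 1000.0, 2000.0, 2000.0, 2000.0]
        trace = e.simulate_closed_loop(
            0.98e-3, circuit, n_periods=5, load_schedule=schedule
        )
        # period 2 sees the new load with the old amplitude; period 3 is back
        # within one ADC LSB on the shunt current plus one DAC register step
        adc_lsb_a = (2 * circuit.adc_range_v / 2**circuit.adc_bits) / circuit.shunt_resistance_ohm
        assert abs(trace[2].current_true_a - 0.98e-3) > 0.2e-3
        assert abs(trace[3].current_true_a - 0.98e-3) <= adc_lsb_a + 0.005e-3

    def test_unreachable_setpoint(self):
        circuit = e.LoadCircuit(load_resistance_ohm=100_000.0)
        with pytest.raises(e.UnreachableSetpointError):
            e.simulate_closed_loop(0.98e-3, circuit, n_periods=3)

    def test_adc_quantizer_is_midrise(self):
        circuit = e.LoadCircuit(load_resistance_ohm=1000.0)
        step = 2 * circuit.adc_range_v / 2**circuit.adc_bits
        assert _adc_quantize(0.0, circuit) == pytest.approx(step / 2)
        assert abs(_adc_quantize(0.0909, circuit) - 0.0909) <= step / 2


class TestDemodulation:
    def test_pure_cosine(self):
        t = np.arange(55)
        x = 2.0 * np.cos(2 * np.pi * t / 55)
        assert e.rms_demodulate(x, 55) == pytest.approx(2.0 / np.sqrt(2), rel=5e-3)

    def test_zero_signal(self):
        assert e.rms_demodulate(np.zeros(110), 55) == 0.0

    def test_matches_brute_force_on_quantized_period(self):
        period = e.quantize_period(0.98, 40.0, CFG)
        x = period.load_voltage_samples
        brute = math.sqrt(sum(v * v for v in x) / len(x))
        assert e.rms_demodulate(x, 55) == brute

    @pytest.mark.parametrize("bad", [np.array([]), np.ones(54)])
    def test_rejects_bad_lengths(self, bad):
        with pytest.raises(ValueError):
            e.rms_demodulate(bad, 55)

    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=55, max_size=55
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_rms_equals_oracle(self, samples):
        x = np.array(samples)
        oracle = math.sqrt(sum(v * v for v in samples) / 55)
        assert e.rms_demodulate(x, 55) == pytest.approx(oracle, abs=1e-12)


class TestHarmonicDistortion:
    def test_thd_decreases_with_register_ceiling(self):
        """Autoranging rationale: more register headroom, less distortion."""
        thds = []
        for ceiling in (63, 127, 191, 255):
            v = (ceiling + 0.5) * 31.875e-6 * 20e3 / 255
            period = e.quantize_period(v, 20.0, CFG)
            assert period.registers_plus.max() == ceiling
            thds.append(e.harmonic_distortion(period.load_voltage_samples))
        assert all(a > b for a, b in zip(thds, thds[1:]))

    def test_pure_cosine_has_negligible_thd(self):
        x = np.cos(2 * np.pi * np.arange(55) / 55)
        assert e.harmonic_distortion(x) < 1e-10
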