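"""Quantized signal-generation and amplitude-control chain.

The device synthesizes a cosine current by writing an 8-bit register table
to two current DACs (one per half-wave) once per sample; trans-impedance
amplifiers convert the currents to a bipolar load voltage
``VL = R_fb * (I2 - I1)``.  The feedback resistance ``R_fb`` is switched
("autoranged") with the requested amplitude so the register table always
spans most of the 8-bit range, and a once-per-period multiplicative control
law drives the load-current amplitude to a setpoint without knowing the
load: ``a[k] = a[k-1] * Id / IL[k]``, starting from ``a[0] = 1 V``.

All public quantities use the device's bench units: register counts are
dimensionless integers, DAC currents are in microamperes, feedback
resistances in kiloohms, voltages in volts, load currents in amperes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DDSConfig",
    "FeedbackRange",
    "ControlState",
    "SampledPeriod",
    "LoadCircuit",
    "PeriodRecord",
    "UnreachableSetpointError",
    "DEFAULT_FEEDBACK_RANGE",
    "select_feedback_resistor",
    "quantize_period",
    "idac_current",
    "tia_output",
    "update_amplitude",
    "simulate_closed_loop",
    "rms_demodulate",
    "harmonic_distortion",
]

# Guard added before flooring: the register scale factors are exact decimals
# (e.g. 255*0.15/0.6375 = 60) that land a few ulp below the integer in
# binary floating point.  1e-9 is far below half of one register LSB.
_FLOOR_GUARD = 1e-9


class UnreachableSetpointError(ValueError):
    """The requested current needs a voltage the DDS cannot produce."""


@dataclass(frozen=True)
class DDSConfig:
    """Direct-digital-synthesizer configuration.

    Parameters
    ----------
    samples_per_period:
        Register updates per period of the cosine (device default 55).
    idac_full_scale_ua:
        Current, in microamperes, produced at the maximum register value.
    register_max:
        Largest register value; ``2**bits - 1`` for an 8-bit DAC.
    signal_frequency_hz:
        Cosine frequency in hertz.  The simulator is frequency-agnostic
        (one period is one abstract time unit) but the device range is
        validated.
    reference_voltage_v:
        Optional fixed virtual-ground reference ``Vr`` for the TIAs.  When
        ``None`` a per-period value with headroom is chosen automatically.
    """

    samples_per_period: int = 55
    idac_full_scale_ua: float = 31.875
    register_max: int = 255
    signal_frequency_hz: float = 50_000.0
    reference_voltage_v: float | None = None

    def __post_init__(self) -> None:
        if self.samples_per_period < 2:
            raise ValueError("samples_per_period must be >= 2")
        if self.register_max < 1 or (self.register_max + 1) & self.register_max:
            raise ValueError("register_max must be 2**bits - 1")
        if self.idac_full_scale_ua <= 0:
            raise ValueError("idac_full_scale_ua must be positive")
        if not (2.0 <= self.signal_frequency_hz <= 50_000.0):
            raise ValueError("signal_frequency_hz outside device range 2 Hz - 50 kHz")


@dataclass(frozen=True)
class FeedbackRange:
    """Autoranging table: rows of (lower V incl., upper V excl., R_fb kΩ)."""

    rows: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_upper = None
        prev_r = -math.inf
        for lower, upper, r_fb in self.rows:
            if upper <= lower:
                raise ValueError("each row needs lower < upper")
            if prev_upper is not None and not math.isclose(lower, prev_upper):
                raise ValueError("rows must be contiguous and sorted")
            if r_fb <= prev_r:
                raise ValueError("R_fb must increase with the voltage range")
            prev_upper, prev_r = upper, r_fb

    @property
    def v_min(self) -> float:
        return self.rows[0][0]

    @property
    def v_max(self) -> float:
        return self.rows[-1][1]


#: Feedback resistance as a function of the requested amplitude.  The spans
#: are chosen so the register ceiling stays in the upper part of the 8-bit
#: range (60..255 for the first five rows, 122..148 for the last).
DEFAULT_FEEDBACK_RANGE = FeedbackRange(
    rows=(
        (0.15000, 0.63750, 20.0),
        (0.63750, 0.95625, 30.0),
        (0.95625, 1.27500, 40.0),
        (1.27500, 2.55000, 80.0),
        (2.55000, 3.82500, 120.0),
        (3.82500, 4.62500, 250.0),
    )
)


@dataclass(frozen=True)
class ControlState:
    """State of the once-per-period amplitude controller."""

    amplitude_v: float = 1.0
    desired_current_a: float = 1e-3
    period_index: int = 0
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_v <= 0:
            raise ValueError("amplitude must be positive")
        if self.desired_current_a <= 0:
            raise ValueError("desired current must be positive")


@dataclass(frozen=True)
class SampledPeriod:
    """One quantized period: register tables and the analog load voltage."""

    registers_plus: np.ndarray
    registers_minus: np.ndarray
    load_voltage_samples: np.ndarray
    r_fb_kohm: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if np.any((self.registers_plus != 0) & (self.registers_minus != 0)):
            raise ValueError("at most one DAC register may be nonzero per sample")


@dataclass(frozen=True)
class LoadCircuit:
    """Resistive load in series with the current-sense shunt and its ADC."""

    load_resistance_ohm: float
    shunt_resistance_ohm: float = 100.0
    adc_bits: int = 10
    adc_range_v: float = 2.048  # half-range of the differential SAR ADC

    def __post_init__(self) -> None:
        if self.load_resistance_ohm <= 0 or self.shunt_resistance_ohm <= 0:
            raise ValueError("resistances must be positive")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")


def select_feedback_resistor(
    v: float, table: FeedbackRange = DEFAULT_FEEDBACK_RANGE
) -> float:
    """Return the feedback resistance (kΩ) for amplitude ``v`` (volts).

    Raises ``ValueError`` when ``v`` lies outside the autoranging span.
    """
    for lower, upper, r_fb in table.rows:
        if lower <= v < upper:
            return r_fb
    raise ValueError(
        f"amplitude {v:g} V outside the DDS span [{table.v_min:g}, {table.v_max:g}) V"
    )


def _register_scale(v: float, r_fb_kohm: float, cfg: DDSConfig) -> float:
    return cfg.register_max * v / (cfg.idac_full_scale_ua * 1e-6 * r_fb_kohm * 1e3)


def quantize_period(
    v: float, r_fb_kohm: float, cfg: DDSConfig = DDSConfig()
) -> SampledPeriod:
    """Quantize one cosine period of amplitude ``v`` into DAC registers.

    For sample ``i`` with ``Si = cos(2*pi*i/n)`` the two register tables are
    ``D± = floor(scale * max(0, ±Si))`` with
    ``scale = register_max * v / (idac_full_scale * R_fb)``; the positive
    table drives the lower TIA and the negative table the upper one, so the
    reconstructed load voltage is ``VL_i = R_fb*(I(D+_i) - I(D-_i))``.
    """
    if v <= 0:
        raise ValueError("amplitude must be positive")
    scale = _register_scale(v, r_fb_kohm, cfg)
    saturated = scale > cfg.register_max + 1
    i = np.arange(cfg.samples_per_period)
    s = np.cos(2.0 * np.pi * i / cfg.samples_per_period)
    d_plus = np.floor(scale * np.maximum(0.0, s) + _FLOOR_GUARD).astype(np.int64)
    d_minus = np.floor(scale * np.maximum(0.0, -s) + _FLOOR_GUARD).astype(np.int64)
    np.clip(d_plus, 0, cfg.register_max, out=d_plus)
    np.clip(d_minus, 0, cfg.register_max, out=d_minus)
    i_plus = d_plus * (cfg.idac_full_scale_ua / cfg.register_max) * 1e-6
    i_minus = d_minus * (cfg.idac_full_scale_ua / cfg.register_max) * 1e-6
    vl = r_fb_kohm * 1e3 * (i_plus - i_minus)
    return SampledPeriod(
        registers_plus=d_plus,
        registers_minus=d_minus,
        load_voltage_samples=vl,
        r_fb_kohm=r_fb_kohm,
        saturated=saturated,
    )


def idac_current(register: int, cfg: DDSConfig = DDSConfig()) -> float:
    """Current (µA) generated for an integer register value."""
    if not float(register).is_integer():
        raise ValueError("register must be an integer")
    register = int(register)
    if not 0 <= register <= cfg.register_max:
        raise ValueError(f"register must be in [0, {cfg.register_max}]")
    return register * cfg.idac_full_scale_ua / cfg.register_max


def tia_output(
    i1_ua: float, i2_ua: float, r_fb_kohm: float, vr_v: float
) -> tuple[float, float, float]:
    """Trans-impedance stage outputs ``(Va, Vb, VL)`` in volts.

    ``Va = Vr - R_fb*I1`` and ``Vb = Vr - R_fb*I2`` must stay positive on
    the single-supply device, which bounds the reference voltage from below.
    """
    r = r_fb_kohm * 1e3
    vr_min = r * max(i1_ua, i2_ua) * 1e-6
    if vr_v <= vr_min:
        raise ValueError(
            f"reference voltage {vr_v:g} V too low; needs Vr > {vr_min:g} V"
        )
    va = vr_v - r * i1_ua * 1e-6
    vb = vr_v - r * i2_ua * 1e-6
    return va, vb, r * (i2_ua - i1_ua) * 1e-6


def update_amplitude(
    state: ControlState,
    measured_amplitude_a: float,
    table: FeedbackRange = DEFAULT_FEEDBACK_RANGE,
) -> ControlState:
    """One step of the multiplicative control law ``a' = a * Id / IL``.

    The new amplitude is clamped to the DDS-feasible span, with
    ``clipped=True`` flagging saturation.
    """
    if measured_amplitude_a <= 0:
        raise ValueError("no load current sensed (IL <= 0): open circuit?")
    a_new = state.amplitude_v * state.desired_current_a / measured_amplitude_a
    clipped = False
    v_hi = np.nextafter(table.v_max, 0.0)
    if a_new < table.v_min:
        a_new, clipped = table.v_min, True
    elif a_new > v_hi:
        a_new, clipped = v_hi, True
    return replace(
        state,
        amplitude_v=a_new,
        period_index=state.period_index + 1,
        clipped=clipped,
    )


def _adc_quantize(v: float, circuit: LoadCircuit) -> float:
    """Mid-rise uniform quantizer over the differential ADC range."""
    step = 2.0 * circuit.adc_range_v / 2**circuit.adc_bits
    v = float(np.clip(v, -circuit.adc_range_v, circuit.adc_range_v - step))
    return step * (math.floor(v / step) + 0.5)


@dataclass(frozen=True)
class PeriodRecord:
    """Per-period trace entry of the closed-loop simulation."""

    period_index: int
    amplitude_v: float
    r_fb_kohm: float
    current_true_a: float
    current_measured_a: float
    clipped: bool = False


def simulate_closed_loop(
    desired_current_a: float,
    circuit: LoadCircuit,
    cfg: DDSConfig = DDSConfig(),
    n_periods: int = 4,
    table: FeedbackRange = DEFAULT_FEEDBACK_RANGE,
    load_schedule: Sequence[float] | None = None,
) -> list[PeriodRecord]:
    """Simulate the closed current-control loop for ``n_periods`` periods.

    Each period: autorange ``R_fb`` from the requested amplitude, quantize
    the cosine, read the shunt voltage at the waveform peak through the SAR
    ADC, divide by the shunt to estimate the current amplitude, and apply
    the control law.  ``load_schedule`` optionally overrides the load
    resistance per period (e.g. to model a load step).

    Because ``a' = a*Id/IL`` cancels the (unknown) load, the true current
    amplitude reaches ``Id`` in the second period up to DAC/ADC
    quantization.
    """
    if n_periods < 2:
        raise ValueError("n_periods must be >= 2")
    if desired_current_a <= 0:
        raise ValueError("desired current must be positive")
    if load_schedule is not None and len(load_schedule) != n_periods:
        raise ValueError("load_schedule must have one resistance per period")

    r_series = circuit.load_resistance_ohm + circuit.shunt_resistance_ohm
    v_req = desired_current_a * r_series
    if not (table.v_min <= v_req < table.v_max):
        raise UnreachableSetpointError(
            f"setpoint needs {v_req:g} V, outside the DDS span "
            f"[{table.v_min:g}, {table.v_max:g}) V"
        )

    state = ControlState(amplitude_v=1.0, desired_current_a=desired_current_a)
    # peak of the quantized cosine sits at sample argmax |Si| = 0
    trace: list[PeriodRecord] = []
    for k in range(n_periods):
        rl = circuit.load_resistance_ohm if load_schedule is None else load_schedule[k]
        r_fb = select_feedback_resistor(state.amplitude_v, table)
        period = quantize_period(state.amplitude_v, r_fb, cfg)
        peak = int(np.argmax(np.abs(period.load_voltage_samples)))
        vl_peak = float(period.load_voltage_samples[peak])
        i_true = vl_peak / (rl + circuit.shunt_resistance_ohm)
        v_shunt = _adc_quantize(i_true * circuit.shunt_resistance_ohm, circuit)
        i_meas = v_shunt / circuit.shunt_resistance_ohm
        trace.append(
            PeriodRecord(
                period_index=k,
                amplitude_v=state.amplitude_v,
                r_fb_kohm=r_fb,
                current_true_a=i_true,
                current_measured_a=i_meas,
                clipped=state.clipped,
            )
        )
        state = update_amplitude(state, i_meas, table)
    return trace


def rms_demodulate(waveform: np.ndarray, samples_per_period: int = 55) -> float:
    """RMS of a waveform covering a whole number of periods."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if waveform.size % samples_per_period:
        raise ValueError(
            f"waveform length {waveform.size} is not a multiple of "
            f"{samples_per_period} samples per period"
        )
    return float(np.sqrt(np.mean(waveform**2)))


def harmonic_distortion(period_samples: np.ndarray) -> float:
    """Total harmonic distortion of one period (non-fundamental/fundamental RMS).

    Computed from the discrete Fourier decomposition of the period; the DC
    bin is excluded from both numerator and denominator.
    """
    x = np.asarray(period_samples, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    spec = np.abs(np.fft.rfft(x))
    fundamental = spec[1]
    if fundamental == 0:
        raise ValueError("no fundamental component")
    rest = np.sqrt(np.sum(spec[2:] ** 2))
    return float(rest / fundamental)
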