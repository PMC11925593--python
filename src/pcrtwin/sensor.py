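"""LM35 + ADC measurement chain and water-bath calibration.

The block and lid temperatures are read by LM35C linear sensors
(nominally 10 mV/°C over −40…+110 °C) through a 10-bit ADC referenced at
5 V, i.e. a least-significant-bit step of ~4.88 mV.  Calibration against
a water bath yields a linear law

    T = (Vout + a) / b

with offset ``a`` (mV) and sensitivity ``b`` (mV/°C) estimated by
ordinary least squares of sensor voltage on bath temperature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: LM35C variant measurement range, °C.
SENSOR_RANGE_C = (-40.0, 110.0)


class CalibrationError(ValueError):
    """Raised for degenerate or invalid calibration data."""


@dataclass(frozen=True)
class AdcConfig:
    """Analog-to-digital converter settings.

    Parameters
    ----------
    reference_voltage : float
        Full-scale reference, millivolts (default 5000 mV = 5 V).
    bits : int
        Resolution in bits (default 10).
    """

    reference_voltage: float = 5000.0
    bits: int = 10

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError(f"bits must be >= 1, got {self.bits}")
        if self.reference_voltage <= 0:
            raise ValueError("reference_voltage must be positive")

    @property
    def lsb_voltage(self) -> float:
        """Voltage step per count, mV."""
        return self.reference_voltage / 2 ** self.bits


@dataclass(frozen=True)
class SensorCalibration:
    """Linear sensor law ``T = (Vout + a) / b``.

    ``a`` is the offset in mV, ``b`` the sensitivity in mV/°C.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise CalibrationError(f"sensitivity b must be > 0, got {self.b}")


@dataclass(frozen=True)
class SensorNoise:
    """Additive Gaussian measurement noise, expressed in °C."""

    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass(frozen=True)
class CalibrationSample:
    """One water-bath observation: known temperature and sensor voltage."""

    true_temp: float
    vout: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.true_temp) and math.isfinite(self.vout)):
            raise ValueError("calibration sample values must be finite")


def adc_lsb_voltage(adc: AdcConfig) -> float:
    """Voltage resolution of the ADC in mV per count."""
    return adc.lsb_voltage


def quantize(voltage: float, adc: AdcConfig) -> float:
    """Quantize a voltage (mV) to the nearest ADC level.

    Out-of-range voltages are clamped to [0, reference] with a warning,
    mirroring how a real converter rails.
    """
    if voltage < 0.0 or voltage > adc.reference_voltage:
        logger.warning(
            "ADC input %.3f mV outside [0, %.0f] mV; clamping",
            voltage, adc.reference_voltage,
        )
        voltage = min(max(voltage, 0.0), adc.reference_voltage)
    lsb = adc.lsb_voltage
    # floor(x + 0.5): round-half-up, platform independent
    return math.floor(voltage / lsb + 0.5) * lsb


def temp_to_voltage(true_temp: float, cal: SensorCalibration) -> float:
    """Ideal (noise-free, unquantized) sensor output, mV."""
    return cal.b * true_temp - cal.a


def voltage_to_temp(vout: float, cal: SensorCalibration) -> float:
    """Invert the calibration law: ``T = (vout + a) / b``."""
    if not (cal.b > 0):
        raise CalibrationError("invalid calibration: b must be > 0")
    return (vout + cal.a) / cal.b


def measure_voltage(
    true_temp: float,
    cal: SensorCalibration,
    adc: AdcConfig | None,
    noise: SensorNoise | None,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulate the sensor/ADC voltage (mV) for one reading.

    The chain is: clamp to the sensor range, convert to voltage, add
    Gaussian voltage noise (sd given in °C and scaled by the sensitivity),
    and quantize through the ADC (pass ``adc=None`` to disable).
    Deterministic for a fixed ``rng`` state.
    """
    lo, hi = SENSOR_RANGE_C
    if true_temp < lo or true_temp > hi:
        logger.warning("temperature %.2f °C outside sensor range; clamping", true_temp)
        true_temp = min(max(true_temp, lo), hi)
    vout = temp_to_voltage(true_temp, cal)
    if noise is not None and noise.gaussian_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise sd > 0")
        vout += rng.normal(0.0, noise.gaussian_sd * cal.b)
    if adc is not None:
        vout = quantize(vout, adc)
    return vout


def measure(
    true_temp: float,
    cal: SensorCalibration,
    adc: AdcConfig | None,
    noise: SensorNoise | None,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulate one temperature reading, °C.

    :func:`measure_voltage` followed by inversion of the calibration law.
    """
    return voltage_to_temp(measure_voltage(true_temp, cal, adc, noise, rng), cal)


def fit_calibration(samples: list[CalibrationSample]) -> SensorCalibration:
    """Least-squares fit of the linear sensor law.

    Regresses voltage on bath temperature (the controlled variable) and
    maps the regression line ``vout = b*T - a`` back to the calibration
    constants: ``b`` is the slope, ``a`` minus the intercept.
    """
    temps = np.array([s.true_temp for s in samples], dtype=float)
    volts = np.array([s.vout for s in samples], dtype=float)
    if len(np.unique(temps)) < 2:
        raise CalibrationError(
            "calibration fit needs at least 2 samples at distinct temperatures"
        )
    slope, intercept = np.polyfit(temps, volts, 1)
    return SensorCalibration(a=-float(intercept), b=float(slope))


@dataclass(frozen=True)
class CalibrationErrorReport:
    """Measurement-error summary over a temperature grid."""

    max_abs_error: float
    mean_abs_error: float
    n_measurements: int
    grid: tuple[float, ...] = field(repr=False, default=())


def calibration_error_report(
    cal: SensorCalibration,
    adc: AdcConfig | None,
    noise: SensorNoise | None,
    grid: list[float],
    n_per_point: int = 20,
    rng: np.random.Generator | None = None,
) -> CalibrationErrorReport:
    """Monte-Carlo measurement-error survey across a temperature grid.

    Simulates ``n_per_point`` readings at each grid temperature and
    reports the max and mean absolute deviation from truth, °C.
    """
    if len(grid) == 0:
        raise ValueError("grid must contain at least one temperature")
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    errors = []
    for t in grid:
        for _ in range(n_per_point):
            errors.append(abs(measure(t, cal, adc, noise, rng) - t))
    arr = np.array(errors)
    return CalibrationErrorReport(
        max_abs_error=float(arr.max()),
        mean_abs_error=float(arr.mean()),
        n_measurements=arr.size,
        grid=tuple(grid),
    )
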