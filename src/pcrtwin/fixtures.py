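"""Reference configurations and synthetic data sets.

Two kinds of artifacts live here:

* Accessors for the packaged reference configuration (block and lid
  plant parameters, sensor chain, 30-cycle protocol, noiseless
  calibration data) under ``pcrtwin/data/``.  The block parameters are
  the output of :func:`pcrtwin.plant.fit_plant_to_observables` against
  the instrument's characterized ramp observables.
* Generators for synthetic data sets with closed-form properties
  (collinear calibration points, analytic temperature traces), used to
  validate the calibration fit and the metrics layer against exact
  answers.

``make_all`` regenerates every packaged file deterministically;
regeneration is byte-stable.
"""

from __future__ import annotations

import importlib.resources
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .engine import TRACE_COLUMNS, Protocol, ProtocolStage, SimulationConfig
from .pid import ScheduledController
from .plant import PlantParams, fit_plant_to_observables
from .sensor import (
    AdcConfig,
    CalibrationSample,
    SensorCalibration,
    SensorNoise,
    measure_voltage,
)

#: Files that make up the packaged reference configuration.
DATA_FILES = (
    "reference_block.yaml",
    "reference_lid.yaml",
    "reference_sensor.yaml",
    "protocol_pcr30.yaml",
    "calibration_noiseless.csv",
)

#: Block start temperature of the characterized first heating ramp, °C.
REFERENCE_START_TEMP_C = 26.39

#: Gaussian measurement noise used in sensor error studies, °C.
STUDY_NOISE_SD_C = 0.08

#: Water-bath temperature grid for calibration and error studies, °C.
STUDY_GRID_C = tuple(30.0 + 5.0 * i for i in range(15))


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(importlib.resources.files("pcrtwin.data") / name)


def reference_block_params() -> PlantParams:
    """Fitted block plant parameters shipped with the package."""
    return _io.load_plant_params(data_path("reference_block.yaml"))


def reference_lid_params() -> PlantParams:
    """Resistive heated-lid plant parameters shipped with the package."""
    return _io.load_plant_params(data_path("reference_lid.yaml"))


def reference_sensor_config() -> _io.SensorConfig:
    """Calibrated LM35 + 10-bit ADC chain shipped with the package."""
    return _io.load_sensor_config(data_path("reference_sensor.yaml"))


def reference_protocol() -> tuple[Protocol, dict[str, ScheduledController]]:
    """Standard 30-cycle PCR protocol plus its gain schedule."""
    return _io.load_protocol(data_path("protocol_pcr30.yaml"))


def reference_simulation_config(
    seed: int = 0, with_noise: bool = False
) -> SimulationConfig:
    """Simulation config assembled from the packaged reference files.

    The reference closed-loop profile keeps ADC quantization on but
    measurement noise off, so protocol-level figures are deterministic;
    pass ``with_noise=True`` to add the study-level Gaussian noise.
    """
    sensor = reference_sensor_config()
    noise = SensorNoise(STUDY_NOISE_SD_C, seed) if with_noise else sensor.noise
    protocol, schedule = reference_protocol()
    return SimulationConfig(
        block=reference_block_params(),
        lid=reference_lid_params(),
        calibration=sensor.calibration,
        adc=sensor.adc,
        noise=noise,
        schedule=schedule,
        seed=seed,
        start_temp=REFERENCE_START_TEMP_C,
    )


# ---------------------------------------------------------------------------
# Synthetic calibration data
# ---------------------------------------------------------------------------


def make_calibration_samples(
    calibration: SensorCalibration | None = None,
    grid: list[float] | None = None,
    n_per_point: int = 1,
    noise: SensorNoise | None = None,
    adc: AdcConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[CalibrationSample]:
    """Simulated water-bath calibration samples.

    With the defaults (no noise, no ADC) the points are exactly
    collinear, so the least-squares fit must recover the generating
    constants to floating-point precision.
    """
    calibration = calibration or SensorCalibration(a=19.50, b=10.14)
    grid = grid if grid is not None else list(STUDY_GRID_C)
    if noise is not None and noise.gaussian_sd > 0 and rng is None:
        rng = np.random.default_rng(noise.seed)
    samples = []
    for t in grid:
        for _ in range(n_per_point):
            vout = measure_voltage(t, calibration, adc, noise, rng)
            samples.append(CalibrationSample(true_temp=t, vout=vout))
    return samples


# ---------------------------------------------------------------------------
# Analytic traces with closed-form metrics
# ---------------------------------------------------------------------------


def _trace_frame(time, temp, label, target_lid=105.0, lid=None) -> pd.DataFrame:
    n = len(time)
    return pd.DataFrame(
        {
            "time_s": time,
            "block_true_C": temp,
            "block_measured_C": temp,
            "lid_C": lid if lid is not None else np.full(n, target_lid),
            "pwm": np.zeros(n, dtype=int),
            "direction": np.array(["idle"] * n),
            "stage_label": np.array([label] * n),
            "cycle_index": np.zeros(n, dtype=int),
        }
    )[list(TRACE_COLUMNS)]


def make_linear_ramp_trace(
    start: float = 55.0,
    target: float = 95.0,
    rate: float = 2.0,
    dt: float = 0.1,
    extra_hold: float = 10.0,
) -> pd.DataFrame:
    """A constant-rate ramp followed by a perfect hold.

    Closed forms: ramp duration ``(target-start)/rate``; average and
    maximum rate both equal ``rate``; hold error zero.
    """
    ramp_time = (target - start) / rate
    n = int(round((ramp_time + extra_hold) / dt)) + 1
    time = np.round(np.arange(n) * dt, 6)
    temp = np.minimum(start + rate * time, target)
    return _trace_frame(time, temp, "denaturation")


def make_sine_hold_trace(
    target: float = 72.0,
    amplitude: float = 0.5,
    period: float = 20.0,
    duration: float = 120.0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """A hold oscillating sinusoidally about its target.

    Closed forms: max |error| = amplitude; mean error ~ 0 over whole
    periods; overshoot = amplitude.
    """
    n = int(round(duration / dt)) + 1
    time = np.round(np.arange(n) * dt, 6)
    temp = target + amplitude * np.sin(2 * math.pi * time / period)
    return _trace_frame(time, temp, "extension")


def make_triangle_lid_trace(
    setpoint: float = 105.0,
    amplitude: float = 1.0,
    period: float = 30.0,
    duration: float = 300.0,
    dt: float = 0.1,
    start: float = 25.0,
    rise_rate: float = 1.0,
) -> pd.DataFrame:
    """A lid trace: linear rise to the setpoint, then a triangle wave.

    Closed form: settled max deviation = amplitude.
    """
    rise_time = (setpoint - start) / rise_rate
    n = int(round((rise_time + duration) / dt)) + 1
    time = np.round(np.arange(n) * dt, 6)
    lid = np.where(
        time < rise_time,
        start + rise_rate * time,
        setpoint
        + amplitude
        * (2.0 / math.pi)
        * np.arcsin(np.sin(2 * math.pi * (time - rise_time) / period)),
    )
    block = np.full(n, 72.0)
    return _trace_frame(time, block, "extension", lid=lid)


# ---------------------------------------------------------------------------
# Regenerating the packaged reference files
# ---------------------------------------------------------------------------


def standard_protocol() -> Protocol:
    """The 30-cycle protocol the reference configuration ships with."""
    return Protocol(
        initial_denaturation=ProtocolStage("initial_denaturation", 95.0, 180.0),
        cycle_block=(
            ProtocolStage("denaturation", 95.0, 15.0),
            ProtocolStage("annealing", 55.0, 15.0),
            ProtocolStage("extension", 72.0, 60.0),
        ),
        cycles=30,
        final_extension=ProtocolStage("final_extension", 72.0, 300.0),
        lid_setpoint=105.0,
    )


def make_reference_configs(out_dir: str | Path, refit: bool = False) -> None:
    """Write the reference YAML configs into ``out_dir``.

    By default the committed fitted block parameters are written; with
    ``refit=True`` the grid-search fit is re-run from the ramp
    observables (a few seconds) and its output written instead.  Both
    paths produce identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if refit:
        block = fit_plant_to_observables(probe_cycles=3).params
        block = PlantParams(
            gain_heat=round(block.gain_heat, 4),
            gain_cool=round(block.gain_cool, 4),
            pump_droop=round(block.pump_droop, 5),
            loss_coeff=round(block.loss_coeff, 5),
            ambient=block.ambient,
        )
    else:
        block = PlantParams(
            gain_heat=2.815,
            gain_cool=4.18,
            pump_droop=0.004,
            loss_coeff=0.002,
            ambient=25.0,
        )
    # Full-power equilibrium at ambient + gain/loss = 220 °C, the lid's
    # unregulated dry-fire ceiling; gain_cool is never exercised (the
    # thermostat only switches the heater) and mirrors gain_heat.
    lid = PlantParams(
        gain_heat=1.2, gain_cool=1.2, pump_droop=0.0, loss_coeff=0.00615, ambient=25.0
    )
    _io.save_plant_params(block, out / "reference_block.yaml")
    _io.save_plant_params(lid, out / "reference_lid.yaml")
    _io.save_sensor_config(
        _io.SensorConfig(
            calibration=SensorCalibration(a=19.50, b=10.14), adc=AdcConfig()
        ),
        out / "reference_sensor.yaml",
    )
    _io.save_protocol(standard_protocol(), out / "protocol_pcr30.yaml")


def make_all(out_dir: str | Path) -> list[Path]:
    """Regenerate every packaged data file in ``out_dir``; returns paths."""
    out = Path(out_dir)
    make_reference_configs(out)
    samples = make_calibration_samples()
    _io.write_calibration_csv(samples, out / "calibration_noiseless.csv")
    return [out / name for name in DATA_FILES]
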