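"""Closed-loop PCR protocol simulation.

Expands a protocol into its stage sequence and runs the loop:

* the block sensor is read (with calibration, noise and ADC
  quantization) once per controller period;
* the PID controller for the current stage kind converts the error into
  a signed PWM command, held between controller updates;
* the block plant integrates at the (finer) simulation step;
* the heated lid runs concurrently under an on/off hysteresis
  thermostat — the lid needs no PID, slight deviations do not matter.

A stage's hold timer starts when the *measured* temperature first
enters the hold entry band around the target, and the stage ends when
the hold has elapsed.  PID state is reset at every stage transition,
matching the picture of five separate stage controllers and
suppressing derivative kick at setpoint changes.  The hold timer does
not pause if the temperature later leaves the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pid as _pid
from . import sensor as _sensor
from .pid import DEFAULT_SCHEDULE, ScheduledController
from .plant import PlantParams, PlantState, plant_step

#: Column order of a temperature trace.
TRACE_COLUMNS = (
    "time_s",
    "block_true_C",
    "block_measured_C",
    "lid_C",
    "pwm",
    "direction",
    "stage_label",
    "cycle_index",
)


class ProtocolError(ValueError):
    """Raised for invalid protocol definitions."""


class StalledProtocolError(RuntimeError):
    """A stage failed to reach its hold entry band within the timeout."""


@dataclass(frozen=True)
class ProtocolStage:
    """One temperature stage: kind, target (°C) and hold duration (s)."""

    kind: str
    target: float
    hold: float
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _pid.STAGE_KINDS:
            raise ProtocolError(f"unknown stage kind {self.kind!r}")
        if self.hold <= 0:
            raise ProtocolError("hold duration must be positive")


@dataclass(frozen=True)
class Protocol:
    """A full PCR thermal protocol.

    ``cycle_block`` (denaturation, annealing, extension) is repeated
    ``cycles`` times between the initial denaturation and the final
    extension.  The lid setpoint defaults to 105 °C.
    """

    initial_denaturation: ProtocolStage
    cycle_block: tuple[ProtocolStage, ...]
    cycles: int
    final_extension: ProtocolStage
    lid_setpoint: float = 105.0

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ProtocolError("cycles must be >= 0")


@dataclass(frozen=True)
class LidThermostat:
    """On/off hysteresis law for the resistive heated lid."""

    setpoint: float = 105.0
    hysteresis_band: float = 2.0

    def __post_init__(self) -> None:
        if self.hysteresis_band <= 0:
            raise ProtocolError("hysteresis_band must be positive")


def lid_step(th: LidThermostat, lid_temp: float, heating: bool) -> bool:
    """Next binary lid drive: on below band, off above band, else hold."""
    if lid_temp < th.setpoint - th.hysteresis_band / 2:
        return True
    if lid_temp > th.setpoint + th.hysteresis_band / 2:
        return False
    return heating


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the closed loop needs besides the protocol itself.

    dt : float
        Plant integration step, s.
    control_period : float
        Controller sampling period, s; the PID coefficients use raw
        per-sample sums and differences, so they are tied to this value.
    start_temp : float | None
        Initial block temperature (°C); defaults to the plant ambient.
    hold_entry_band : float
        Half-width of the band (°C) whose first entry starts a hold.
    """

    block: PlantParams
    lid: PlantParams
    calibration: _sensor.SensorCalibration
    adc: _sensor.AdcConfig | None = None
    noise: _sensor.SensorNoise | None = None
    schedule: dict[str, ScheduledController] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULE)
    )
    dt: float = 0.1
    control_period: float = 1.0
    seed: int = 0
    start_temp: float | None = None
    lid_start_temp: float | None = None
    hold_entry_band: float = 1.0
    lid_hysteresis_band: float = 2.0
    stall_timeout: float = 300.0
    integral_separation: float = _pid.INTEGRAL_SEPARATION_C

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ProtocolError("dt must be positive")
        if self.control_period < self.dt:
            raise ProtocolError("control_period must be >= dt")


def expand_protocol(p: Protocol) -> list[ProtocolStage]:
    """Ordered stage list: initial denaturation, cycles, final extension."""
    stages = [replace(p.initial_denaturation, cycle_index=0)]
    for c in range(1, p.cycles + 1):
        stages.extend(replace(s, cycle_index=c) for s in p.cycle_block)
    stages.append(replace(p.final_extension, cycle_index=p.cycles + 1))
    return stages


def stage_targets(p: Protocol) -> dict[str, float]:
    """Stage-kind → target map for the metrics layer."""
    targets = {
        p.initial_denaturation.kind: p.initial_denaturation.target,
        p.final_extension.kind: p.final_extension.target,
    }
    targets.update({s.kind: s.target for s in p.cycle_block})
    return targets


def run_protocol(p: Protocol, cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate the full closed loop; returns the temperature trace.

    The trace is uniformly sampled at ``cfg.dt`` with the columns in
    :data:`TRACE_COLUMNS`.  ``block_measured_C`` holds the most recent
    sensor reading (updated once per controller period), ``pwm`` the
    signed command currently applied to the Peltier drive.
    """
    stages = expand_protocol(p)
    rng = np.random.default_rng(cfg.seed)
    thermostat = LidThermostat(p.lid_setpoint, cfg.lid_hysteresis_band)

    block = PlantState(
        temp=cfg.start_temp if cfg.start_temp is not None else cfg.block.ambient
    )
    lid = PlantState(
        temp=cfg.lid_start_temp if cfg.lid_start_temp is not None else cfg.lid.ambient
    )
    lid_on = False

    steps_per_control = max(1, round(cfg.control_period / cfg.dt))

    times: list[float] = []
    true_temps: list[float] = []
    meas_temps: list[float] = []
    lid_temps: list[float] = []
    pwms: list[int] = []
    directions: list[str] = []
    labels: list[str] = []
    cycle_idx: list[int] = []

    measured = _sensor.measure(block.temp, cfg.calibration, cfg.adc, cfg.noise, rng)

    for stage in stages:
        row = _pid.select_gains(cfg.schedule, stage.kind)
        state = _pid.reset()
        command = _pid.DriveCommand(0, "idle")
        in_hold = False
        hold_elapsed = 0.0
        stage_elapsed = 0.0
        tick = 0

        while True:
            if tick % steps_per_control == 0:
                measured = _sensor.measure(
                    block.temp, cfg.calibration, cfg.adc, cfg.noise, rng
                )
                command, state = _pid.pid_step(
                    row.gains, state, stage.target, measured,
                    integral_separation=cfg.integral_separation,
                )
            if not in_hold and abs(measured - stage.target) <= cfg.hold_entry_band:
                in_hold = True

            times.append(block.time)
            true_temps.append(block.temp)
            meas_temps.append(measured)
            lid_temps.append(lid.temp)
            pwms.append(command.signed)
            directions.append(command.direction)
            labels.append(stage.kind)
            cycle_idx.append(stage.cycle_index)

            lid_on = lid_step(thermostat, lid.temp, lid_on)
            lid = plant_step(lid, _pid.PWM_MAX if lid_on else 0, cfg.dt, cfg.lid)
            block = plant_step(block, command.signed, cfg.dt, cfg.block)

            tick += 1
            stage_elapsed += cfg.dt
            if in_hold:
                hold_elapsed += cfg.dt
                if hold_elapsed >= stage.hold - 0.5 * cfg.dt:
                    break
            elif stage_elapsed > cfg.stall_timeout:
                raise StalledProtocolError(
                    f"stage {stage.kind!r} (cycle {stage.cycle_index}) never "
                    f"reached {stage.target} ± {cfg.hold_entry_band} °C within "
                    f"{cfg.stall_timeout} s"
                )

    return pd.DataFrame(
        {
            "time_s": np.round(np.asarray(times), 6),
            "block_true_C": true_temps,
            "block_measured_C": meas_temps,
            "lid_C": lid_temps,
            "pwm": pwms,
            "direction": directions,
            "stage_label": labels,
            "cycle_index": cycle_idx,
        }
    )


def run_lid_only(cfg: SimulationConfig, setpoint: float, duration: float) -> pd.DataFrame:
    """Simulate only the heated lid under its thermostat for ``duration`` s."""
    thermostat = LidThermostat(setpoint, cfg.lid_hysteresis_band)
    lid = PlantState(
        temp=cfg.lid_start_temp if cfg.lid_start_temp is not None else cfg.lid.ambient
    )
    lid_on = False
    times, temps = [], []
    n = int(round(duration / cfg.dt))
    for _ in range(n):
        times.append(lid.time)
        temps.append(lid.temp)
        lid_on = lid_step(thermostat, lid.temp, lid_on)
        lid = plant_step(lid, _pid.PWM_MAX if lid_on else 0, cfg.dt, cfg.lid)
    return pd.DataFrame({"time_s": np.round(np.asarray(times), 6), "lid_C": temps})
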