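"""Reading and writing configs, traces, calibration data and reports.

File formats
------------
* Plant, sensor and protocol configs are YAML with explicit units in
  the key names.
* Temperature traces are CSV with the exact column set
  :data:`pcrtwin.engine.TRACE_COLUMNS`.
* Calibration data sets are two-column CSV (``true_temp_C,vout_mV``).
* Performance reports serialize to JSON (machine-readable) and to a
  human-readable text table.

All writers round-trip: loading what was saved reproduces the original
object (floats are written with ``repr`` precision).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import metrics as _metrics
from .engine import TRACE_COLUMNS, Protocol, ProtocolStage
from .pid import DEFAULT_SCHEDULE, PidGains, ScheduledController
from .plant import PlantParams
from .sensor import AdcConfig, CalibrationSample, SensorCalibration, SensorNoise


class ConfigError(ValueError):
    """Raised when a config file is malformed or missing required keys."""


def _load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at top level")
    return data


def _require(data: dict, key: str, path: str | Path):
    try:
        return data[key]
    except KeyError:
        raise ConfigError(f"{path}: missing required key {key!r}") from None


# ---------------------------------------------------------------------------
# Plant configs
# ---------------------------------------------------------------------------


def save_plant_params(params: PlantParams, path: str | Path) -> None:
    doc = {
        "gain_heat_C_per_s": params.gain_heat,
        "gain_cool_C_per_s": params.gain_cool,
        "pump_droop_per_s": params.pump_droop,
        "loss_coeff_per_s": params.loss_coeff,
        "ambient_C": params.ambient,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_plant_params(path: str | Path) -> PlantParams:
    data = _load_yaml(path)
    return PlantParams(
        gain_heat=float(_require(data, "gain_heat_C_per_s", path)),
        gain_cool=float(_require(data, "gain_cool_C_per_s", path)),
        pump_droop=float(data.get("pump_droop_per_s", 0.0)),
        loss_coeff=float(data.get("loss_coeff_per_s", 0.0)),
        ambient=float(data.get("ambient_C", 25.0)),
    )


# ---------------------------------------------------------------------------
# Sensor configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorConfig:
    """Calibration plus optional ADC and noise blocks, as stored on disk."""

    calibration: SensorCalibration
    adc: AdcConfig | None = None
    noise: SensorNoise | None = None


def save_sensor_config(cfg: SensorConfig, path: str | Path) -> None:
    doc: dict = {
        "calibration": {"a_mV": cfg.calibration.a, "b_mV_per_C": cfg.calibration.b}
    }
    if cfg.adc is not None:
        doc["adc"] = {
            "reference_voltage_mV": cfg.adc.reference_voltage,
            "bits": cfg.adc.bits,
        }
    if cfg.noise is not None:
        doc["noise"] = {"gaussian_sd_C": cfg.noise.gaussian_sd}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_sensor_config(path: str | Path) -> SensorConfig:
    data = _load_yaml(path)
    cal = _require(data, "calibration", path)
    calibration = SensorCalibration(
        a=float(_require(cal, "a_mV", path)), b=float(_require(cal, "b_mV_per_C", path))
    )
    adc = None
    if "adc" in data:
        adc = AdcConfig(
            reference_voltage=float(data["adc"].get("reference_voltage_mV", 5000.0)),
            bits=int(data["adc"].get("bits", 10)),
        )
    noise = None
    if "noise" in data:
        sd = float(data["noise"].get("gaussian_sd_C", 0.0))
        if sd > 0:
            noise = SensorNoise(gaussian_sd=sd)
    return SensorConfig(calibration=calibration, adc=adc, noise=noise)


# ---------------------------------------------------------------------------
# Protocol configs
# ---------------------------------------------------------------------------


def _stage_doc(stage: ProtocolStage) -> dict:
    return {"kind": stage.kind, "target_C": stage.target, "hold_s": stage.hold}


def _stage_from_doc(doc: dict, path: str | Path, kind: str | None = None) -> ProtocolStage:
    return ProtocolStage(
        kind=str(doc["kind"]) if kind is None else kind,
        target=float(_require(doc, "target_C", path)),
        hold=float(_require(doc, "hold_s", path)),
    )


def save_protocol(
    p: Protocol,
    path: str | Path,
    schedule: dict[str, ScheduledController] | None = None,
) -> None:
    doc: dict = {
        "initial_denaturation": {
            "target_C": p.initial_denaturation.target,
            "hold_s": p.initial_denaturation.hold,
        },
        "cycle": [_stage_doc(s) for s in p.cycle_block],
        "cycles": p.cycles,
        "final_extension": {
            "target_C": p.final_extension.target,
            "hold_s": p.final_extension.hold,
        },
        "lid_setpoint_C": p.lid_setpoint,
    }
    if schedule is not None:
        doc["gain_overrides"] = {
            kind: {"kp": row.gains.kp, "ki": row.gains.ki, "kd": row.gains.kd}
            for kind, row in schedule.items()
            if row.gains != DEFAULT_SCHEDULE[kind].gains
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_protocol(
    path: str | Path,
) -> tuple[Protocol, dict[str, ScheduledController]]:
    """Load a protocol plus its (possibly overridden) gain schedule."""
    data = _load_yaml(path)
    init = _stage_from_doc(
        _require(data, "initial_denaturation", path), path, kind="initial_denaturation"
    )
    cycle = tuple(
        _stage_from_doc(doc, path) for doc in _require(data, "cycle", path)
    )
    final = _stage_from_doc(
        _require(data, "final_extension", path), path, kind="final_extension"
    )
    protocol = Protocol(
        initial_denaturation=init,
        cycle_block=cycle,
        cycles=int(_require(data, "cycles", path)),
        final_extension=final,
        lid_setpoint=float(data.get("lid_setpoint_C", 105.0)),
    )
    schedule = dict(DEFAULT_SCHEDULE)
    for kind, g in (data.get("gain_overrides") or {}).items():
        if kind not in schedule:
            raise ConfigError(f"{path}: gain override for unknown stage {kind!r}")
        schedule[kind] = ScheduledController(
            pid_id=schedule[kind].pid_id,
            gains=PidGains(float(g["kp"]), float(g["ki"]), float(g["kd"])),
            target=schedule[kind].target,
        )
    # Retarget the schedule rows to the protocol's setpoints.
    stage_map = {init.kind: init.target, final.kind: final.target}
    stage_map.update({s.kind: s.target for s in cycle})
    for kind, tgt in stage_map.items():
        row = schedule[kind]
        schedule[kind] = ScheduledController(row.pid_id, row.gains, tgt)
    return protocol, schedule


# ---------------------------------------------------------------------------
# Traces and calibration data
# ---------------------------------------------------------------------------


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ConfigError(f"trace is missing columns {missing}")
    trace.loc[:, list(TRACE_COLUMNS)].to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    trace = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ConfigError(f"{path}: trace is missing columns {missing}")
    return trace


def write_calibration_csv(samples: list[CalibrationSample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "true_temp_C": [s.true_temp for s in samples],
            "vout_mV": [s.vout for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> list[CalibrationSample]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("true_temp_C", "vout_mV"):
        if col not in df.columns:
            raise ConfigError(f"{path}: calibration CSV is missing column {col!r}")
    return [
        CalibrationSample(true_temp=float(t), vout=float(v))
        for t, v in zip(df["true_temp_C"], df["vout_mV"])
    ]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def report_to_dict(report: _metrics.PerformanceReport) -> dict:
    return {
        "ramps": [dataclasses.asdict(r) for r in report.ramps],
        "holds": [dataclasses.asdict(h) for h in report.holds],
        "lid": dataclasses.asdict(report.lid) if report.lid is not None else None,
        "checks": dict(report.checks),
        "passed": report.passed,
    }


def write_report_json(report: _metrics.PerformanceReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
        fh.write("\n")


def format_report_text(report: _metrics.PerformanceReport) -> str:
    lines: list[str] = []
    lines.append("Ramps")
    lines.append(
        f"  {'stage':<22} {'cyc':>3} {'from':>7} {'to':>6} "
        f"{'dur_s':>7} {'avg':>6} {'max':>6}"
    )
    for r in report.ramps:
        flag = " (open)" if r.open_ramp else ""
        lines.append(
            f"  {r.stage_label:<22} {r.cycle_index:>3} {r.start_temp:>7.2f} "
            f"{r.end_target:>6.1f} {r.duration:>7.1f} {r.avg_rate:>6.2f} "
            f"{r.max_rate:>6.2f}{flag}"
        )
    lines.append("Holds")
    lines.append(
        f"  {'stage':<22} {'cyc':>3} {'target':>7} {'max|err|':>9} "
        f"{'mean_err':>9} {'overshoot':>9}"
    )
    for h in report.holds:
        lines.append(
            f"  {h.stage_label:<22} {h.cycle_index:>3} {h.target:>7.1f} "
            f"{h.settled_max_abs_error:>9.3f} {h.mean_error:>+9.3f} "
            f"{h.overshoot:>9.3f}"
        )
    if report.lid is not None:
        lines.append(
            f"Lid: setpoint {report.lid.setpoint:.1f} C, settled max deviation "
            f"{report.lid.settled_max_deviation:.2f} C "
            f"(settled at t={report.lid.settle_time:.1f} s)"
        )
    lines.append("Checks")
    for name, ok in report.checks.items():
        lines.append(f"  {name}: {'PASS' if ok else 'FAIL'}")
    lines.append(f"Overall: {'PASS' if report.passed else 'FAIL'}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def write_manifest(path: str | Path, **fields) -> None:
    """Record how a trace was produced (seed, dt, config paths, version)."""
    from . import __version__

    doc = {"pcrtwin_version": __version__, **fields}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")
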