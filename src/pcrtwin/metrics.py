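"""Performance quantities derived from a temperature trace.

Given a stage-labelled trace (simulated or recorded), this module
computes the figures a thermal-cycler datasheet quotes: ramp durations
and average/maximum rates between setpoints, hold (steady-state) error
statistics, and the heated-lid deviation.

Conventions
-----------
* A ramp spans from the first sample of a stage to the first sample at
  or beyond the new target; the ramp therefore belongs to the stage
  being entered (the cooling ramp belongs to the annealing stage).
* The average rate is the temperature span divided by the (un-rounded)
  duration, matching how such figures are usually quoted.
* The maximum rate is the largest centred moving-window slope with a
  1 s window.  Per-sample differences would be dominated by the sensor
  quantization step (~0.48 °C), so a windowed slope is used instead.
* Hold statistics exclude the first ``settling_exclusion`` seconds
  (default 5 s) after the hold entry-band crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SETTLING_EXCLUSION_S = 5.0
DEFAULT_RATE_WINDOW_S = 1.0
DEFAULT_ENTRY_BAND_C = 1.0


@dataclass(frozen=True)
class RampReport:
    """One setpoint transition: where it started, how fast it got there."""

    stage_label: str
    cycle_index: int
    start_temp: float
    end_target: float
    start_time: float
    duration: float
    avg_rate: float
    max_rate: float
    direction: str  # "heating" | "cooling"
    open_ramp: bool = False  # target never crossed within the stage


@dataclass(frozen=True)
class HoldReport:
    """Steady-state statistics for one hold segment."""

    stage_label: str
    cycle_index: int
    target: float
    hold_duration: float
    settled_max_abs_error: float
    mean_error: float
    overshoot: float


@dataclass(frozen=True)
class LidReport:
    """Post-settling deviation of the heated lid from its setpoint."""

    setpoint: float
    settled_max_deviation: float
    settle_time: float


@dataclass(frozen=True)
class PerformanceThresholds:
    """Pass/fail limits for the QC gate."""

    max_hold_error: float = 1.0
    max_lid_deviation: float = 2.0


@dataclass(frozen=True)
class PerformanceReport:
    ramps: tuple[RampReport, ...]
    holds: tuple[HoldReport, ...]
    lid: LidReport | None
    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def _stage_segments(trace: pd.DataFrame):
    """Yield (label, cycle_index, integer index slice) per stage run."""
    labels = trace["stage_label"].to_numpy()
    cycles = trace["cycle_index"].to_numpy()
    key = np.array([f"{c}:{l}" for l, c in zip(labels, cycles)])
    boundaries = np.flatnonzero(key[1:] != key[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(key)]))
    for s, e in zip(starts, ends):
        yield labels[s], int(cycles[s]), slice(s, e)


def _window_slopes(time: np.ndarray, temp: np.ndarray, window: float) -> np.ndarray:
    """Centred moving-window slope, °C/s; truncated at the edges."""
    if len(time) < 2:
        return np.zeros(len(time))
    dt = float(time[1] - time[0])
    half = max(1, int(round(window / (2 * dt))))
    idx = np.arange(len(time))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, len(time) - 1)
    span = (hi - lo) * dt
    return (temp[hi] - temp[lo]) / np.where(span > 0, span, np.inf)


def detect_ramps(
    trace: pd.DataFrame,
    targets: dict[str, float],
    rate_window: float = DEFAULT_RATE_WINDOW_S,
    entry_band: float = DEFAULT_ENTRY_BAND_C,
    temp_column: str = "block_true_C",
) -> list[RampReport]:
    """Extract one ramp per stage transition that changes the setpoint.

    ``targets`` maps stage labels to setpoints.  Stages that begin
    already inside the entry band produce no ramp.  A stage whose target
    is never crossed yields a report flagged ``open_ramp`` with the
    duration of the whole stage.
    """
    time = trace["time_s"].to_numpy(dtype=float)
    temp = trace[temp_column].to_numpy(dtype=float)
    ramps: list[RampReport] = []
    for label, cyc, seg in _stage_segments(trace):
        tgt = targets[label]
        t_seg, y_seg = time[seg], temp[seg]
        start_temp = y_seg[0]
        if abs(start_temp - tgt) <= entry_band:
            continue
        sign = 1.0 if tgt > start_temp else -1.0
        crossed = np.flatnonzero(sign * (y_seg - tgt) >= 0)
        if len(crossed) == 0:
            logger.warning("stage %s cycle %d: target %.2f never crossed", label, cyc, tgt)
            end = len(y_seg) - 1
            open_ramp = True
        else:
            end = int(crossed[0])
            open_ramp = False
        duration = float(t_seg[end] - t_seg[0])
        slopes = sign * _window_slopes(t_seg[: end + 1], y_seg[: end + 1], rate_window)
        ramps.append(
            RampReport(
                stage_label=str(label),
                cycle_index=cyc,
                start_temp=float(start_temp),
                end_target=float(tgt),
                start_time=float(t_seg[0]),
                duration=duration,
                avg_rate=abs(tgt - start_temp) / duration if duration > 0 else float("nan"),
                max_rate=float(slopes.max()) if len(slopes) else float("nan"),
                direction="heating" if sign > 0 else "cooling",
                open_ramp=open_ramp,
            )
        )
    return ramps


def hold_statistics(
    trace: pd.DataFrame,
    targets: dict[str, float],
    settling_exclusion: float = DEFAULT_SETTLING_EXCLUSION_S,
    entry_band: float = DEFAULT_ENTRY_BAND_C,
    temp_column: str = "block_true_C",
) -> list[HoldReport]:
    """Steady-state error statistics for every hold in the trace.

    A hold starts at the stage's first entry into ``±entry_band`` of its
    target; the first ``settling_exclusion`` seconds are dropped before
    computing the max absolute and mean signed errors.  Overshoot is the
    peak excursion beyond the target, in the approach direction, over
    the whole stage.
    """
    if settling_exclusion < 0:
        raise ValueError("settling_exclusion must be >= 0")
    time = trace["time_s"].to_numpy(dtype=float)
    temp = trace[temp_column].to_numpy(dtype=float)
    holds: list[HoldReport] = []
    for label, cyc, seg in _stage_segments(trace):
        tgt = targets[label]
        t_seg, y_seg = time[seg], temp[seg]
        inside = np.flatnonzero(np.abs(y_seg - tgt) <= entry_band)
        if len(inside) == 0:
            logger.warning("stage %s cycle %d has no hold segment", label, cyc)
            continue
        entry = int(inside[0])
        sign = 1.0 if y_seg[0] <= tgt else -1.0
        overshoot = float(max(0.0, (sign * (y_seg - tgt)).max()))
        hold_t = t_seg[entry:] - t_seg[entry]
        hold_y = y_seg[entry:]
        settled = hold_y[hold_t >= settling_exclusion]
        if len(settled) == 0:
            logger.warning(
                "hold %s cycle %d shorter than the %.1f s settling exclusion; "
                "using the full hold", label, cyc, settling_exclusion,
            )
            settled = hold_y
        err = settled - tgt
        holds.append(
            HoldReport(
                stage_label=str(label),
                cycle_index=cyc,
                target=float(tgt),
                hold_duration=float(hold_t[-1]) if len(hold_t) else 0.0,
                settled_max_abs_error=float(np.abs(err).max()),
                mean_error=float(err.mean()),
                overshoot=overshoot,
            )
        )
    return holds


def lid_statistics(
    trace: pd.DataFrame, setpoint: float, lid_column: str = "lid_C"
) -> LidReport:
    """Max |lid − setpoint| after the lid first crosses its setpoint."""
    if lid_column not in trace.columns:
        raise KeyError(f"trace has no {lid_column!r} column")
    time = trace["time_s"].to_numpy(dtype=float)
    lid = trace[lid_column].to_numpy(dtype=float)
    start_sign = np.sign(lid[0] - setpoint) or 1.0
    crossed = np.flatnonzero(np.sign(lid - setpoint) != start_sign)
    if len(crossed) == 0:
        raise ValueError("lid never crossed the setpoint; nothing has settled")
    i = int(crossed[0])
    return LidReport(
        setpoint=float(setpoint),
        settled_max_deviation=float(np.abs(lid[i:] - setpoint).max()),
        settle_time=float(time[i]),
    )


def performance_report(
    trace: pd.DataFrame,
    targets: dict[str, float],
    lid_setpoint: float | None = None,
    thresholds: PerformanceThresholds | None = None,
    settling_exclusion: float = DEFAULT_SETTLING_EXCLUSION_S,
) -> PerformanceReport:
    """Full ramp/hold/lid report with pass-fail checks against thresholds."""
    thresholds = thresholds or PerformanceThresholds()
    ramps = detect_ramps(trace, targets)
    holds = hold_statistics(trace, targets, settling_exclusion=settling_exclusion)
    lid = lid_statistics(trace, lid_setpoint) if lid_setpoint is not None else None
    checks = {
        "all_holds_within_threshold": bool(
            holds
            and max(h.settled_max_abs_error for h in holds) <= thresholds.max_hold_error
        ),
        "no_open_ramps": not any(r.open_ramp for r in ramps),
    }
    if lid is not None:
        checks["lid_within_threshold"] = (
            lid.settled_max_deviation <= thresholds.max_lid_deviation
        )
    return PerformanceReport(tuple(ramps), tuple(holds), lid, checks)
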