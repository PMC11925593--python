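"""Discrete gain-scheduled PID law with 8-bit saturation.

Each PCR stage runs its own PID coefficient triple (the "piecewise
variable coefficient" scheme).  The control signal for sample ``n`` is

    E(n) = Tt(n) - Ts(n)
    I(n) = sum_i E(i)          (raw sample sum, conditional on saturation)
    D(n) = E(n) - E(n-1)       (raw sample difference)
    U(n) = Kp*E(n) + Ki*I(n) + Kd*D(n)

The magnitude is saturated to the 8-bit PWM range [0, 255] and the sign
of U selects the heat/cool current direction through the H-bridge.
Because I and D are raw per-sample sums/differences, the coefficients
are tied to the controller sampling period (1 s by default, recorded in
the simulation config).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: Full-scale PWM command, counts.
PWM_MAX = 255

#: Safety clamp on the integral term's contribution, counts.  Conditional
#: integration already suspends wind-up at saturation; the clamp bounds the
#: state against pathological gain choices.
INTEGRAL_TERM_LIMIT = 2.0 * PWM_MAX

#: Integral separation band, °C: the integral only accumulates once the
#: error is inside this band.  Far from the setpoint the loop is slew-rate
#: limited and any accumulated integral would only discharge as overshoot;
#: near the setpoint the integral trims the residual droop.
INTEGRAL_SEPARATION_C = 8.0

STAGE_KINDS = (
    "initial_denaturation",
    "denaturation",
    "annealing",
    "extension",
    "final_extension",
)


@dataclass(frozen=True)
class PidGains:
    """Proportional/integral/derivative coefficients (dimensionless)."""

    kp: float
    ki: float
    kd: float

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("PID gains must be non-negative")


@dataclass(frozen=True)
class PidState:
    """Controller memory between samples."""

    integral: float = 0.0
    prev_error: float = 0.0
    initialized: bool = False


@dataclass(frozen=True)
class DriveCommand:
    """Saturated PWM magnitude plus H-bridge direction."""

    magnitude: int
    direction: str  # "heat" | "cool" | "idle"

    def __post_init__(self) -> None:
        if not (0 <= self.magnitude <= PWM_MAX):
            raise ValueError("magnitude outside [0, 255]")
        if (self.direction == "idle") != (self.magnitude == 0):
            raise ValueError("direction is idle iff magnitude is 0")

    @property
    def signed(self) -> int:
        """Signed PWM counts: positive heats, negative cools."""
        return self.magnitude if self.direction != "cool" else -self.magnitude


@dataclass(frozen=True)
class ScheduledController:
    """One row of the gain schedule: controller id, gains, stage target."""

    pid_id: str
    gains: PidGains
    target: float


#: Stage-wise coefficient schedule: five controllers, one per PCR stage.
DEFAULT_SCHEDULE: dict[str, ScheduledController] = {
    "initial_denaturation": ScheduledController("PID1", PidGains(15, 1, 7), 95.0),
    "denaturation": ScheduledController("PID2", PidGains(15, 1, 7), 95.0),
    "annealing": ScheduledController("PID3", PidGains(9, 0.1, 5), 55.0),
    "extension": ScheduledController("PID4", PidGains(13, 1, 10), 72.0),
    "final_extension": ScheduledController("PID5", PidGains(13, 1, 10), 72.0),
}


def select_gains(
    schedule: dict[str, ScheduledController], stage_kind: str
) -> ScheduledController:
    """Look up the controller row for a PCR stage kind."""
    try:
        return schedule[stage_kind]
    except KeyError:
        raise KeyError(
            f"unknown stage kind {stage_kind!r}; expected one of {STAGE_KINDS}"
        ) from None


def reset(state: PidState | None = None) -> PidState:
    """Zeroed controller state; used at every stage transition."""
    return PidState()


def pid_step(
    gains: PidGains,
    state: PidState,
    target: float,
    measured: float,
    integral_separation: float = INTEGRAL_SEPARATION_C,
) -> tuple[DriveCommand, PidState]:
    """One controller sample: error in, drive command and new state out.

    Anti-windup is two-fold: the integral only accumulates inside the
    integral-separation band around the setpoint, and accumulation is
    suspended while the output is saturated in the direction of the
    error (conditional integration).  On the first sample after a reset
    the previous error is taken as zero, so the derivative contribution
    is ``Kd*E``.
    """
    error = target - measured
    prev = state.prev_error if state.initialized else 0.0
    derivative = error - prev

    integral = state.integral
    if state.initialized and error * state.prev_error < 0:
        # setpoint crossing: the integral built up on approach would only
        # discharge as overshoot, so it is cleared
        integral = 0.0
    if abs(error) <= integral_separation:
        integral = integral + error
    if gains.ki > 0:
        lim = INTEGRAL_TERM_LIMIT / gains.ki
        integral = min(max(integral, -lim), lim)

    u = gains.kp * error + gains.ki * integral + gains.kd * derivative
    if abs(u) > PWM_MAX and u * error > 0:
        # saturated in the error's direction: suspend integral accumulation
        integral = state.integral
        u = gains.kp * error + gains.ki * integral + gains.kd * derivative

    magnitude = min(PWM_MAX, int(round(abs(u))))
    if magnitude == 0:
        direction = "idle"
    elif u > 0:
        direction = "heat"
    else:
        direction = "cool"

    new_state = PidState(integral=integral, prev_error=error, initialized=True)
    return DriveCommand(magnitude=magnitude, direction=direction), new_state
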