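"""Gain-scheduled PID law: closed forms, saturation, anti-windup."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcrtwin.pid import (
    DEFAULT_SCHEDULE,
    INTEGRAL_TERM_LIMIT,
    PWM_MAX,
    DriveCommand,
    PidGains,
    PidState,
    pid_step,
    reset,
    select_gains,
)


def test_schedule_has_five_stage_controllers():
    assert set(DEFAULT_SCHEDULE) == {
        "initial_denaturation",
        "denaturation",
        "annealing",
        "extension",
        "final_extension",
    }
    assert DEFAULT_SCHEDULE["denaturation"].gains == PidGains(15, 1, 7)
    assert DEFAULT_SCHEDULE["annealing"].gains == PidGains(9, 0.1, 5)
    assert DEFAULT_SCHEDULE["extension"].gains == PidGains(13, 1, 10)


def test_select_gains_unknown_stage():
    with pytest.raises(KeyError):
        select_gains(DEFAULT_SCHEDULE, "elongation")


def test_worked_example_pid3():
    # PID3 (9, 0.1, 5), fresh state, target 55, measured 53:
    # E=2, I=2, D=2 -> U = 18 + 0.2 + 10 = 28.2 -> magnitude 28, heat
    cmd, state = pid_step(PidGains(9, 0.1, 5), PidState(), target=55.0, measured=53.0)
    assert cmd.magnitude == 28
    assert cmd.direction == "heat"
    assert state.integral == pytest.approx(2.0)
    assert state.prev_error == pytest.approx(2.0)


def test_saturates_at_255_for_large_error():
    cmd, _ = pid_step(PidGains(15, 1, 7), PidState(), target=95.0, measured=26.39)
    assert cmd.magnitude == PWM_MAX
    assert cmd.direction == "heat"


def test_zero_error_fresh_state_is_idle():
    cmd, _ = pid_step(PidGains(15, 1, 7), PidState(), target=72.0, measured=72.0)
    assert cmd.magnitude == 0
    assert cmd.direction == "idle"


def test_reset_clears_state():
    _, state = pid_step(PidGains(15, 1, 7), PidState(), 95.0, 90.0)
    assert state.initialized
    fresh = reset(state)
    assert fresh == PidState()


@given(
    kp=st.floats(0.1, 50),
    target=st.floats(20, 100),
    measured=st.floats(20, 100),
)
def test_pure_p_closed_form(kp, target, measured):
    """With Ki=Kd=0 the command is exactly min(255, |Kp*E|) with sign(E)."""
    cmd, _ = pid_step(PidGains(kp, 0, 0), PidState(), target, measured)
    u = kp * (target - measured)
    assert cmd.magnitude == min(PWM_MAX, round(abs(u)))
    if cmd.magnitude > 0:
        assert cmd.direction == ("heat" if u > 0 else "cool")


@given(
    kp=st.floats(0.5, 30),
    ki=st.floats(0, 2),
    kd=st.floats(0, 15),
    target=st.floats(20, 100),
    measured=st.floats(20, 100),
)
def test_sign_correctness_fresh_state(kp, ki, kd, target, measured):
    cmd, _ = pid_step(PidGains(kp, ki, kd), PidState(), target, measured)
    if measured < target:
        assert cmd.direction in ("heat", "idle")
    elif measured > target:
        assert cmd.direction in ("cool", "idle")


@given(
    errors=st.lists(st.floats(-80, 80), min_size=1, max_size=60),
    ki=st.floats(0.05, 2),
)
def test_output_always_within_pwm_range(errors, ki):
    gains = PidGains(15, ki, 7)
    state = PidState()
    for e in errors:
        cmd, state = pid_step(gains, state, target=e, measured=0.0)
        assert 0 <= cmd.magnitude <= PWM_MAX
        # the integral term contribution stays clamped
        assert abs(ki * state.integral) <= INTEGRAL_TERM_LIMIT + 1e-9


def test_conditional_integration_suspends_windup_at_saturation():
    gains = PidGains(15, 1, 0)
    state = PidState()
    # constant in-band error of 5 °C: P term 75, integral grows each step
    # until saturation, then freezes
    integrals = []
    for _ in range(80):
        cmd, state = pid_step(gains, state, target=5.0, measured=0.0)
        integrals.append(state.integral)
    assert cmd.magnitude == PWM_MAX
    # once saturated in the error's direction, the integral stops growing
    assert integrals[-1] == integrals[-2]
    assert integrals[-1] <= (PWM_MAX - 15 * 5.0) / 1.0 + 5.0 + 1e-9


def test_integral_separation_blocks_accumulation_far_from_setpoint():
    gains = PidGains(1, 1, 0)
    state = PidState()
    _, state = pid_step(gains, state, target=50.0, measured=0.0,
                        integral_separation=8.0)
    assert state.integral == 0.0
    _, state = pid_step(gains, state, target=5.0, measured=0.0,
                        integral_separation=8.0)
    assert state.integral == pytest.approx(5.0)


def test_integral_resets_on_setpoint_crossing():
    gains = PidGains(1, 0.5, 0)
    state = PidState()
    _, state = pid_step(gains, state, target=2.0, measured=0.0)  # E=+2
    assert state.integral == pytest.approx(2.0)
    _, state = pid_step(gains, state, target=2.0, measured=3.0)  # E=-1: crossed
    assert state.integral == pytest.approx(-1.0)  # cleared, then accumulates -1


def test_derivative_uses_zero_prev_error_on_first_sample():
    cmd_fresh, _ = pid_step(PidGains(0, 0, 5), PidState(), 60.0, 58.0)
    assert cmd_fresh.magnitude == 10  # Kd * (E - 0)
    _, s = pid_step(PidGains(0, 0, 5), PidState(), 60.0, 58.0)
    cmd_second, _ = pid_step(PidGains(0, 0, 5), s, 60.0, 58.0)
    assert cmd_second.magnitude == 0  # E unchanged -> D = 0


def test_drive_command_validation():
    with pytest.raises(ValueError):
        DriveCommand(300, "heat")
    with pytest.raises(ValueError):
        DriveCommand(0, "heat")
    with pytest.raises(ValueError):
        DriveCommand(10, "idle")
    assert DriveCommand(10, "cool").signed == -10


def test_gains_must_be_non_negative():
    with pytest.raises(ValueError):
        PidGains(-1, 0, 0)
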