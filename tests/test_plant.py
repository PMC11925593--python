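"""Thermal plant: rate law, Euler stepping, equilibria, parameter fit."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcrtwin.plant import (
    GridSearchConfig,
    PlantError,
    PlantParams,
    PlantState,
    RampObservables,
    equilibrium_temp,
    fit_plant_to_observables,
    plant_step,
    temperature_rate,
)

REF = PlantParams(
    gain_heat=2.815, gain_cool=4.18, pump_droop=0.004, loss_coeff=0.002, ambient=25.0
)


def test_rate_at_full_heat_from_ambient_equals_gain():
    assert temperature_rate(25.0, 255, REF) == pytest.approx(REF.gain_heat)


def test_rate_at_full_cool_from_ambient_equals_minus_gain():
    assert temperature_rate(25.0, -255, REF) == pytest.approx(-REF.gain_cool)


def test_heating_rate_decreases_with_temperature():
    rates = [temperature_rate(t, 255, REF) for t in (25, 50, 75, 95)]
    assert all(a > b for a, b in zip(rates, rates[1:]))


def test_cooling_is_faster_from_hotter_block():
    # both droop and leak help cooling when the block is above ambient
    assert temperature_rate(95.0, -255, REF) < temperature_rate(55.0, -255, REF)


def test_zero_drive_relaxes_toward_ambient():
    assert temperature_rate(95.0, 0, REF) < 0
    assert temperature_rate(10.0, 0, REF) > 0
    assert temperature_rate(REF.ambient, 0, REF) == 0.0


def test_rejects_overrange_drive():
    with pytest.raises(PlantError):
        temperature_rate(50.0, 300, REF)
    with pytest.raises(PlantError):
        plant_step(PlantState(50.0), -256, 0.1, REF)


def test_plant_step_advances_clock_and_temp():
    s = plant_step(PlantState(25.0, 0.0), 255, 0.1, REF)
    assert s.time == pytest.approx(0.1)
    assert s.temp == pytest.approx(25.0 + REF.gain_heat * 0.1)


def test_equilibrium_matches_rate_zero():
    for u in (255, 128, -64, -255):
        t_eq = equilibrium_temp(u, REF)
        assert temperature_rate(t_eq, u, REF) == pytest.approx(0.0, abs=1e-12)
    assert equilibrium_temp(0, REF) == REF.ambient


def test_equilibrium_requires_some_loss():
    p = PlantParams(gain_heat=2.0, gain_cool=2.0)
    with pytest.raises(PlantError):
        equilibrium_temp(255, p)
    assert equilibrium_temp(0, p) == p.ambient


@given(
    u=st.integers(-255, 255),
    t0=st.floats(0, 110),
    n=st.integers(1, 300),
)
def test_trajectory_bounded_by_equilibria(u, t0, n):
    """Under constant drive, an Euler trajectory with dt well under the
    time constant stays between its start and the equilibrium."""
    state = PlantState(float(t0))
    t_eq = equilibrium_temp(u, REF)
    lo, hi = min(t0, t_eq), max(t0, t_eq)
    for _ in range(n):
        state = plant_step(state, u, 0.1, REF)
        assert lo - 1e-9 <= state.temp <= hi + 1e-9


@given(u=st.integers(-255, 255), t0=st.floats(0, 110))
def test_trajectory_moves_monotonically_toward_equilibrium(u, t0):
    state = PlantState(float(t0))
    t_eq = equilibrium_temp(u, REF)
    prev_dist = abs(state.temp - t_eq)
    for _ in range(50):
        state = plant_step(state, u, 0.1, REF)
        dist = abs(state.temp - t_eq)
        assert dist <= prev_dist + 1e-12
        prev_dist = dist


def test_euler_convergence_halving_dt():
    """Halving dt changes a 120 s full-drive trajectory by < 0.05 °C."""

    def run(dt):
        s = PlantState(25.0)
        for _ in range(int(120 / dt)):
            s = plant_step(s, 255, dt, REF)
        return s.temp

    assert abs(run(0.1) - run(0.05)) < 0.05


def test_params_validation():
    with pytest.raises(PlantError):
        PlantParams(gain_heat=0, gain_cool=1)
    with pytest.raises(PlantError):
        PlantParams(gain_heat=1, gain_cool=1, pump_droop=-0.1)


# --- parameter fitting -----------------------------------------------------

FAST_SEARCH = GridSearchConfig(
    gain_heat=(2.78, 2.86, 0.01),
    pump_droop=(0.0030, 0.0060, 0.0005),
    gain_cool=(4.00, 4.40, 0.05),
)


def test_fit_self_consistency_recovers_known_params():
    """Targets generated by forward-simulating known parameters are
    recovered to within the grid resolution."""
    from pcrtwin.engine import run_protocol, stage_targets
    from pcrtwin.fixtures import reference_simulation_config, standard_protocol
    from pcrtwin.metrics import detect_ramps
    from dataclasses import replace

    true = PlantParams(
        gain_heat=2.82, gain_cool=4.20, pump_droop=0.0045, loss_coeff=0.002
    )
    proto = replace(standard_protocol(), cycles=3)
    cfg = replace(reference_simulation_config(), block=true)
    ramps = detect_ramps(run_protocol(proto, cfg), stage_targets(proto))
    heat = ramps[0]
    cool = next(r for r in ramps if r.direction == "cooling")
    targets = RampObservables(
        heat_duration=heat.duration,
        heat_max_rate=heat.max_rate,
        cool_duration=cool.duration,
    )
    res = fit_plant_to_observables(targets, search=FAST_SEARCH, probe_cycles=2)
    assert res.params.gain_heat == pytest.approx(true.gain_heat, abs=0.02)
    assert res.params.pump_droop == pytest.approx(true.pump_droop, abs=0.001)
    assert res.params.gain_cool == pytest.approx(true.gain_cool, abs=0.11)


def test_fit_heating_only_flags_unconstrained_gain_cool():
    targets = RampObservables(cool_duration=None)
    res = fit_plant_to_observables(targets, search=FAST_SEARCH, probe_cycles=1)
    assert res.params.gain_cool == res.params.gain_heat
    assert any("unconstrained" in w for w in res.warnings)
    assert "cool_duration" not in res.residuals


def test_fit_default_targets_reproduce_printed_ramps(reference_run):
    """The packaged block parameters hit the characterized ramp timings
    within ±1 s on the full protocol."""
    from pcrtwin.metrics import detect_ramps

    _, _, trace, targets = reference_run
    ramps = detect_ramps(trace, targets)
    heat = ramps[0]
    cool = next(r for r in ramps if r.direction == "cooling")
    assert heat.duration == pytest.approx(38.0, abs=1.0)
    assert cool.duration == pytest.approx(26.0, abs=1.0)
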