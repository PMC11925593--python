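# Methods

This note records the model equations, parameter provenance, numerical
choices and known limitations of the digital twin. All figures quoted
here are computed by this package (the test suite and
`scripts/acceptance.py` recompute them).

## 1. Sensor and ADC model (`pcrtwin.sensor`)

The block and lid sensors follow a linear law

```
Vout = b·T − a        T = (Vout + a) / b
```

with offset `a` in mV and sensitivity `b` in mV/°C. The reference
calibration is `a = 19.50 mV`, `b = 10.14 mV/°C`, consistent with an
LM35-class device (nominal 10 mV/°C, usable −40…110 °C; readings are
clamped to that range).

A measurement is simulated as:

1. `Vout = b·T_true − a`;
2. optional Gaussian noise added **in the voltage domain** with
   standard deviation `σ_T · b` (σ_T given in °C; default study value
   0.08 °C);
3. ADC quantization to the nearest level of a 10-bit converter at a
   5 V reference: 1 LSB = 5000/1024 = 4.8828125 mV ≈ 0.4816 °C.
   Rounding is half-up (`floor(x/LSB + 0.5)·LSB`), platform
   independent; out-of-range voltages clamp to the rails with a
   warning;
4. inversion through the calibration law.

Calibration fitting is ordinary least squares of voltage on bath
temperature (the controlled variable), via `numpy.polyfit(deg=1)`;
`b` is the slope and `a` minus the intercept. On the packaged
noiseless, unquantized fixture (30–100 °C in 5 °C steps) the fit
recovers `a = 19.50`, `b = 10.14` to floating-point precision. Under
the study noise profile (σ = 0.08 °C plus quantization, 20 readings at
each of 15 grid points) the maximum absolute measurement error is
≈ 0.40–0.45 °C depending on seed — consistent with the analytic bound
`3σ + LSB/2 ≈ 0.48 °C`.

## 2. Controller (`pcrtwin.pid`)

A discrete PID on raw per-sample sums and differences:

```
E(n) = T_target − T_sensed(n)
I(n) = Σ E(i)                (conditional, see anti-windup)
D(n) = E(n) − E(n−1)         (E(−1) = 0 after a reset)
U(n) = Kp·E(n) + Ki·I(n) + Kd·D(n)
```

The drive magnitude is `min(255, round(|U|))` (8-bit PWM) and the sign
of `U` selects the H-bridge direction (heat / cool / idle at zero).

Gain scheduling: each protocol stage kind runs its own coefficient
set — the "piecewise" controller. Defaults:

| controller | stage(s)                  | target | Kp | Ki  | Kd |
|-----------:|---------------------------|-------:|---:|----:|---:|
| PID1, PID2 | initial/denaturation      |  95 °C | 15 | 1   | 7  |
| PID3       | annealing                 |  55 °C |  9 | 0.1 | 5  |
| PID4, PID5 | extension/final extension |  72 °C | 13 | 1   | 10 |

Controller state is reset at every stage transition (five independent
controllers), which also suppresses derivative kick at setpoint steps.

Because `I` and `D` are raw sums/differences, the coefficients are tied
to the controller sampling period. The twin samples the controller at
**1 Hz** (`control_period = 1.0 s`), at which the tabulated gains are
well behaved; at 10 Hz the same gains are strongly underdamped (the
effective integral gain scales with sampling rate). The PWM command is
held between controller samples (zero-order hold).

Anti-windup, in order of application inside `pid_step`:

1. **Integral reset on setpoint crossing** — when `E` changes sign,
   the integral is cleared: windup accumulated on approach would only
   discharge as overshoot.
2. **Integral separation** — the integral only accumulates when
   `|E| ≤ 8 °C` (module default `INTEGRAL_SEPARATION_C`). Far from the
   setpoint the loop is slew-rate limited and integral action is
   useless; near it, the integral trims the residual droop.
3. **Integral clamp** — `|Ki·I| ≤ 2·255` bounds the state against
   pathological gains.
4. **Conditional integration** — if the output saturates in the
   direction of the error, the accumulation of this sample is undone.

## 3. Block plant (`pcrtwin.plant`)

One lumped temperature state:

```
dT/dt = d·g(u) − |d|·c·(T − T_amb) − k·(T − T_amb)
```

where `d = u/255` is the signed duty, `g(u)` is `gain_heat` (u ≥ 0) or
`gain_cool` (u < 0) — the full-drive pumping rate at zero offset — `c`
is the **pump droop** (drive-proportional capacity loss, 1/s) and `k`
the passive Newtonian leak (1/s).

Why two loss-like terms: a plain first-order model
(`dT/dt = d·g − k·(T − T_amb)`) cannot simultaneously reproduce (a) the
observed deceleration of the full-drive heating ramp (mean rate well
below the peak rate) and (b) sub-1 °C holds with modest sustained
drive. Deceleration under full drive demands a large `k`; small hold
droop demands a small one. Physically, a thermoelectric module's net
pumping capacity genuinely degrades as the hot/cold side differential
grows — that is a drive-side effect, present only while current flows.
Splitting the losses into a drive-proportional droop `c` plus a small
passive leak `k` resolves the conflict.

### Fitted reference parameters

`fit_plant_to_observables` fits `(gain_heat, pump_droop, gain_cool)` by
a deterministic sequential grid search, one closed-loop probe
simulation per grid point, against the instrument's characterized
observables (first heating ramp 26.39 → 95 °C in 38 s, peak heating
rate 2.8 °C/s over a 1 s window, first cooling ramp ~95 → 55 °C in
26 s). The probe protocol replicates the reference hold structure,
because hold durations set the controller state at each ramp's start.
The search is near-triangular: `gain_heat` dominates the peak rate,
`pump_droop` the total heating duration, `gain_cool` only the cooling
ramps. `loss_coeff` is not identifiable from ramp timings (its effect
is swamped by the droop whenever the drive is on) and is fixed at
0.002 /s, a passive-leak value consistent with the observed hold
drives; a heating-only target set leaves `gain_cool` unconstrained and
is flagged.

Packaged result (regenerable with `pcrtwin make-fixtures --refit`):

| parameter    | value  | units | role                          |
|--------------|-------:|-------|-------------------------------|
| `gain_heat`  | 2.815  | °C/s  | full-drive heating rate at ambient |
| `gain_cool`  | 4.18   | °C/s  | full-drive cooling rate at ambient |
| `pump_droop` | 0.004  | 1/s   | drive-proportional capacity loss |
| `loss_coeff` | 0.002  | 1/s   | passive leak to ambient       |
| `ambient`    | 25.0   | °C    | surroundings                  |

Closed-loop results with these parameters (full 30-cycle protocol,
start 26.39 °C): initial heating ramp 37.6 s (avg 1.82 °C/s, max
2.80 °C/s), first cooling ramp 25.8 s (avg 1.54 °C/s), worst settled
hold error 0.58 °C over all 92 holds, lid deviation 1.05 °C.

### Integration

Explicit Euler at `dt = 0.1 s`. The fastest system rate constant is
`|d|·c + k ≤ 0.006 /s`, so `dt·λ ≈ 6×10⁻⁴` — deep inside the stability
and accuracy region. The test suite checks that halving `dt` changes a
120 s full-drive trajectory by < 0.05 °C.

## 4. Heated lid (`pcrtwin.engine.lid_step`)

The lid is a resistive (PTC) element: constant power when on, so its
plant uses `pump_droop = 0`, `gain_heat = 1.2 °C/s`,
`loss_coeff = 0.00615 /s`. These values encode a full-power unregulated
equilibrium of `25 + 1.2/0.00615 ≈ 220 °C`, the dry-fire ceiling of
such lids. Control is an on/off thermostat with a 2 °C hysteresis band
centred on the 105 °C setpoint — no PID is needed; slight deviations at
the lid do not matter. Simulated at the plant step (0.1 s). The
600 s lid-only run settles with a maximum post-crossing deviation of
1.05 °C, within the ±2 °C requirement.

## 5. Protocol engine (`pcrtwin.engine`)

A protocol is `initial_denaturation + cycles × (denaturation,
annealing, extension) + final_extension` plus a lid setpoint. The
packaged protocol: 95 °C 180 s; 30 × (95 °C 15 s, 55 °C 15 s, 72 °C
60 s); 72 °C 300 s; lid 105 °C. The initial-denaturation and
final-extension hold durations are conventional choices for a 30-cycle
protocol (the instrument's printed protocol leaves them unstated).

A stage's hold timer starts when the **measured** temperature first
enters ±1 °C of the target (`hold_entry_band`) and runs to completion
regardless of later excursions; a stage that never enters its band
within `stall_timeout` (300 s) raises an error. Traces are uniformly
sampled at `dt` with columns
`time_s, block_true_C, block_measured_C, lid_C, pwm, direction,
stage_label, cycle_index`.

### Reference noise profile

The packaged reference profile keeps ADC quantization **on** and
Gaussian measurement noise **off**, so every protocol-level figure is
exactly reproducible run-to-run; Gaussian noise (σ = 0.08 °C) is used
in the sensor-error study and available everywhere via
`--noise-sd` / `SensorNoise`. With noise enabled the ramp timings
acquire a seed-dependent jitter of roughly ±1 s (the loop can creep
asymptotically through the last quantization step of a ramp).

## 6. Metrics (`pcrtwin.metrics`)

* A **ramp** spans from a stage's first sample to the first sample at
  or beyond the new target; stages starting inside ±1 °C of target
  yield no ramp; never-crossing stages are flagged `open_ramp`.
* `avg_rate = |ΔT| / duration` (un-rounded duration).
* `max_rate` is the largest centred moving-window slope with a 1 s
  window: per-sample differences would be dominated by the ~0.48 °C
  quantization step of the measured channel, and a window matches how
  an instantaneous rate is read off a recorded trace. Applied to the
  true-temperature channel by default.
* **Hold** statistics start at the first entry into ±1 °C of target
  and drop the first 5 s (settling exclusion) before computing max
  absolute and mean signed error; overshoot is the peak excursion
  beyond target in the approach direction over the whole stage.
* **Lid** deviation is `max |T_lid − setpoint|` after the first
  setpoint crossing.
* The QC gate checks all holds ≤ 1 °C, lid ≤ 2 °C, and no open ramps.

## 7. What the generators emulate (`pcrtwin.fixtures`)

* `make_calibration_samples` emulates a water-bath calibration session:
  known bath temperatures on a grid, recorded sensor voltages with
  configurable noise/quantization. The packaged fixture is noiseless
  and unquantized, hence exactly collinear — the regression must
  recover the generating constants exactly.
* `make_linear_ramp_trace`, `make_sine_hold_trace`,
  `make_triangle_lid_trace` construct traces whose metrics have closed
  forms (duration, rates, max error, deviation), used as exact oracles
  for the metrics layer.
* `make_reference_configs` writes the reference YAMLs; with `--refit`
  it re-runs the plant fit. Regeneration is deterministic and
  byte-stable (tested).

## 8. Known limitations

* **Peak cooling rate.** The single-state plant, fitted to the cooling
  *duration*, front-loads the cooling power: its 1 s-window peak
  cooling rate is ≈ 4.6 °C/s, whereas the physical instrument's
  cooling is flatter (≈ 2.2 °C/s peak). Matching both the 26 s duration
  and the flat profile would need a second thermal state (block vs.
  heat-sink) — out of scope; the duration was chosen as the binding
  observable.
* The printed average heating rate of the instrument (1.78 °C/s) is
  mutually inconsistent with its printed span/duration
  ((95 − 26.39)/38 = 1.81 °C/s); the twin reproduces the duration and
  accepts a 2–3 % discrepancy on the average.
* Single lumped block temperature: no cross-well uniformity, no sample
  (tube content) thermal lag.
* No amplification chemistry: yields/product concentrations are out of
  scope.
* The controller runs at 1 Hz by design (see §2); the tabulated gains
  are not transferable to other sampling periods without rescaling.
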