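# pcrtwin

A hardware-free digital twin of a portable, Arduino-class PCR thermal
cycler: a Peltier-driven heating block under a gain-scheduled PID
controller, an LM35 + 10-bit-ADC measurement chain, and a resistive
heated lid under an on/off thermostat. The package simulates complete
PCR thermal protocols (denaturation / annealing / extension cycling),
analyzes the resulting temperature traces, and ships a calibrated
reference configuration that reproduces the characterized performance
of the physical instrument.

## What it models

A polymerase chain reaction thermocycler repeatedly shuttles a sample
block between three temperatures (typically 95 °C, 55 °C and 72 °C).
The twin closes the same loop the firmware does, once per second:

1. **Sensor** — the block temperature is read through a linear
   LM35-style law `Vout = b·T − a` (reference calibration
   `a = 19.50 mV`, `b = 10.14 mV/°C`), optionally perturbed by Gaussian
   voltage noise, and quantized by a 10-bit ADC at a 5 V reference
   (1 LSB = 4.883 mV ≈ 0.48 °C).
2. **Controller** — a stage-scheduled PID (`U = Kp·E + Ki·ΣE + Kd·ΔE`
   on raw per-sample sums/differences) with five coefficient sets, one
   per stage kind. The magnitude saturates to the 8-bit PWM range
   [0, 255] and the sign selects the H-bridge current direction
   (heat / cool). Anti-windup combines conditional integration, an
   integral-separation band and an integral reset at setpoint
   crossings.
3. **Plant** — a lumped first-order thermal model of the block with a
   drive-dependent pumping-capacity droop that captures how a Peltier
   module slows down as the block-to-ambient offset grows
   (see `docs/methods.md`), integrated with explicit Euler at 0.1 s.
4. **Lid** — the heated lid (105 °C setpoint) runs concurrently under
   a ±1 °C hysteresis thermostat on its own resistive-plant model.

The metrics layer turns any stage-labelled trace — simulated or
recorded — into the figures a datasheet quotes: ramp durations,
average/maximum ramp rates, per-hold steady-state error, overshoot and
heated-lid deviation, with a pass/fail QC gate.

With the packaged reference configuration, the twin reproduces the
instrument's headline figures: 26.39 → 95 °C in 38 s (max rate
2.8 °C/s), 95 → 55 °C in 26 s, every hold of a 30-cycle protocol within
1 °C after settling, and the lid within ±2 °C of 105 °C.

## Worked example

Simulate the packaged 30-cycle protocol (3 min initial denaturation at
95 °C; 30 × [95 °C 15 s, 55 °C 15 s, 72 °C 60 s]; 5 min final extension
at 72 °C) and analyze the trace:

```
$ pcrtwin simulate --out demo_trace.csv --seed 0
trace: demo_trace.csv (48470 rows, 4847 s simulated)

$ pcrtwin analyze demo_trace.csv --out demo_report.json
Ramps
  stage                  cyc    from     to   dur_s    avg    max
  initial_denaturation     0   26.39   95.0    37.6   1.82   2.80
  annealing                1   94.62   55.0    25.8   1.54   4.59
  extension                1   54.61   72.0    18.2   0.96   2.63
  denaturation             2   71.53   95.0    20.5   1.15   2.53
  annealing                2   94.46   55.0    26.2   1.51   4.59
...
Lid: setpoint 105.0 C, settled max deviation 1.05 C (settled at t=85.8 s)
Checks
  all_holds_within_threshold: PASS
  no_open_ramps: PASS
  lid_within_threshold: PASS
Overall: PASS
```

`analyze` exits non-zero when a threshold fails, so it can gate a
pipeline; pass `--no-gate` to always exit 0.

The trace CSV is uniformly sampled at 0.1 s:

```
time_s,block_true_C,block_measured_C,lid_C,pwm,direction,stage_label,cycle_index
0.0,26.39,26.481601331360945,25.0,255,heat,initial_denaturation,0
0.1,26.670666,26.481601331360945,25.12,255,heat,initial_denaturation,0
```

Other commands:

```
pcrtwin calibrate samples.csv --out sensor.yaml   # least-squares sensor fit
pcrtwin lid-run --out lid.csv                     # thermostat-only lid run
pcrtwin make-fixtures --out fixtures/             # regenerate reference configs
```

Custom protocols, plants and sensors are plain YAML; see the packaged
files under `src/pcrtwin/data/` for the schema, including per-stage
`gain_overrides`.

### Python API

```python
from pcrtwin import fixtures, run_protocol, stage_targets
from pcrtwin.metrics import performance_report

protocol, _ = fixtures.reference_protocol()
cfg = fixtures.reference_simulation_config()
trace = run_protocol(protocol, cfg)
report = performance_report(trace, stage_targets(protocol), lid_setpoint=105.0)
print(report.passed)  # True
```

## Scope and limitations

Single lumped block temperature (no cross-well gradients), no
amplification chemistry, no hardware I/O. See `docs/methods.md` for the
model derivation, parameter provenance, numerical choices and known
deviations (notably the peak cooling rate, which the simple plant
overestimates).
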