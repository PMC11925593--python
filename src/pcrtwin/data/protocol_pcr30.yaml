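initial_denaturation:
  target_C: 95.0
  hold_s: 180.0
cycle:
- kind: denaturation
  target_C: 95.0
  hold_s: 15.0
- kind: annealing
  target_C: 55.0
  hold_s: 15.0
- kind: extension
  target_C: 72.0
  hold_s: 60.0
cycles: 30
final_extension:
  target_C: 72.0
  hold_s: 300.0
lid_setpoint_C: 105.0
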