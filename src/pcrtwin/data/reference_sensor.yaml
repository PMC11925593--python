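calibration:
  a_mV: 19.5
  b_mV_per_C: 10.14
adc:
  reference_voltage_mV: 5000.0
  bits: 10
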