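gain_heat_C_per_s: 1.2
gain_cool_C_per_s: 1.2
pump_droop_per_s: 0.0
loss_coeff_per_s: 0.00615
ambient_C: 25.0
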