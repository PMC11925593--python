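true_temp_C,vout_mV
30.0,284.70000000000005
35.0,335.40000000000003
40.0,386.1
45.0,436.8
50.0,487.5
55.0,538.2
60.0,588.9000000000001
65.0,639.6
70.0,690.3000000000001
75.0,741.0
80.0,791.7
85.0,842.4000000000001
90.0,893.1
95.0,943.8000000000001
100.0,994.5
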