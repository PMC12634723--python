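participant,placing_total_s,placing_hold_s,placing_hold_pct,turning_total_s,turning_hold_s,turning_hold_pct
P1,62,28.3,45.6,66,30.9,46.8
P2,65,27.1,41.7,69,29.7,43.0
P3,63,34.7,55.1,67,32.1,47.9
P4,57,25.4,44.6,66,28.4,43.0
P5,61,29.8,48.9,76,29.3,38.6
P6,55,19.7,35.8,58,27.3,47.1
P7,56,26.5,47.3,62,33.5,54.0
P8,62,26.1,42.1,67,29.9,44.6
P9,60,32,53.3,64,27.1,42.3
P10,58,31.7,54.7,67,24.3,36.3
P11,59,27.9,47.3,62,30.1,48.5
P12,59,25.1,42.5,67,25.7,38.4
P13,67,24.8,37.0,77,26.1,33.9
P14,64,24.9,38.9,69,35.2,51.0
P15,63,19.6,31.1,69,29.3,42.5
P16,63,24.4,38.7,70,30.3,43.3
P17,68,36.9,54.3,71,26.7,37.6
P18,60,27.3,45.5,64,28.7,44.8
P19,66,23.8,36.1,67,23.1,34.5
P20,65,33,50.8,71,34.8,49.0
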