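participant,x_placing_ms2,x_turning_ms2,y_placing_ms2,y_turning_ms2,z_placing_ms2,z_turning_ms2
P1,2.35,0.8,2.5,1.25,1.05,0.75
P2,2.05,1.1,3.1,0.9,1.4,1.05
P3,2.25,1.15,1.75,0.7,1.1,0.8
P4,2.4,1.15,3.4,0.9,1.2,0.65
P5,2.95,0.75,1.4,0.9,0.95,0.65
P6,2.5,1.5,4.45,1.95,1.75,1.05
P7,1.65,0.9,2.5,1.05,1.3,0.75
P8,1.3,0.75,2.5,0.8,1.2,0.8
P9,1.35,0.95,3.3,1.4,1,0.9
P10,2,1.25,2.9,1.45,1.95,1.3
P11,2.45,0.8,1.85,1.2,1.1,0.85
P12,1.75,0.65,3.45,1.05,1.35,0.65
P13,1.75,0.7,2.7,0.9,1.1,0.6
P14,1.65,0.85,1.95,0.65,1.2,0.65
P15,2.7,1,3.35,1.25,1.35,0.7
P16,2.25,0.75,2.35,1.55,1.4,0.75
P17,2,0.95,2.95,1.35,1.15,0.8
P18,1.9,0.65,2.35,1.8,1.5,0.95
P19,1.95,0.7,1.9,0.95,1.45,0.7
P20,1.85,1.1,2.7,1,1.2,0.9
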