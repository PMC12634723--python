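participant,roll_placing_dps,roll_turning_dps,pitch_placing_dps,pitch_turning_dps,yaw_placing_dps,yaw_turning_dps
P1,94.5,117.5,104,91,193,40.5
P2,153,132,133.5,86.5,222.5,68
P3,70.5,90,132.5,72.5,183,45
P4,135.5,102.5,170.5,68.5,177,96
P5,140.5,130,114.5,58,159.5,84.5
P6,176.5,164,261.5,75.5,177.5,155
P7,119,89,166.5,106,239.5,51
P8,123,130,113.5,118,211.5,52.5
P9,111,81.5,88,80,172,35.5
P10,131,120.5,161,87,199,59
P11,136.5,96.5,164,99,229,48
P12,124.5,126,153,93.5,191,50.5
P13,166,120,106.5,59.5,171.5,47.5
P14,148.5,115,159.5,95.5,203,46
P15,131,91.5,118,115.5,163.5,81
P16,136.5,92.5,123,116,200.5,81
P17,109.5,106.5,167,79.5,175.5,60
P18,130,120.5,103.5,91,170.5,62.5
P19,110.5,92.5,152,66.5,171.5,47
P20,125,83,122,93.5,223,54.5
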