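set,total_time_s,hold_time_classifier_s,hold_time_testrig_s,difference_pct
1,74,31.6,32.8,3.8
2,61,27.6,27.2,1.4
3,64,25.8,26.3,1.9
4,57,23.8,25.5,7.1
5,45,22.1,21.5,2.7
6,44,19.5,19.4,0.5
7,46,21.1,22,4.3
8,40,17.6,18.4,4.5
9,39,19,19.8,4.2
10,43,25.1,26.8,6.8
11,54,32.9,32.2,2.1
12,43,22.6,21.2,6.2
13,55,28.2,28.5,1.1
14,46,21.9,22.8,4.1
15,49,25.1,24.4,2.8
16,48,20.7,20.2,2.4
17,42,21.2,22.6,6.6
18,50,23.1,21.7,6.1
19,48,22.6,21.2,6.2
20,48,21.7,22.4,3.2
21,55,22.3,23.7,6.3
22,71,25.3,24.4,3.6
23,52,20.9,21.2,1.4
24,46,21.6,20.9,3.2
25,48,24.7,25.2,2.0
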