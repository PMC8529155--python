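patient_id,side,gtv_id,optimal_fm_set,margin_rl_mm,margin_ap_mm,margin_is_mm,distances_mm
1,right,1,R3,0.7,0.2,1.0,30.9
1,right,2,R2;R3,1.4,0.9,0.6,69.7;20.3
1,right,3,R2;R3,0.9,0.6,0.7,42.7;33.9
1,right,4,R1,1.2,2.8,3.8,103.7
1,right,5,R2;R3,1.3,0.5,0.8,18.7;68.5
1,right,6,R1;R2,1.0,0.7,1.3,90.4;38.8
1,left,1,L1;L2,3.2,0.9,0.3,52.7;59.3
1,left,2,L1;L2,0.7,0.8,2.0,100.8;11.1
1,left,3,L2,3.3,4.1,4.3,42.0
2,right,1,R2,0.4,0.1,0.4,67.9
3,left,1,L1,0.9,1.9,2.1,39.4
3,left,2,L1,1.0,1.2,2.9,63.0
4,left,1,L2,1.2,0.2,2.9,20.8
5,right,1,R2,0.5,2.7,2.7,41.5
6,right,1,R1,0.8,0.1,4.8,45.5
6,right,2,R1;R2,1.5,0.8,0.4,128.5;52.6
6,right,3,R3,0.3,0.1,4.9,55.6
6,right,4,R2,0.4,0.2,0.4,47.9
7,right,1,R2,0.4,1.1,8.4,52.4
8,right,1,R1;R2,1.3,1.5,3.4,55.3;66.8
8,right,2,R1,1.0,0.5,0.2,69.2
8,right,3,R1,0.3,0.5,0.8,82.4
8,left,1,L1,1.0,1.5,0.1,42.8
9,right,1,R1;R2,0.1,1.7,0.5,59.3;123.8
9,right,2,R1;R2,0.9,0.0,0.4,80.9;91.5
10,right,1,R1,0.6,4.2,3.8,57.5
11,right,1,R1,0.1,0.5,4.4,96.6
11,left,1,L1;L2,1.8,0.3,1.0,19.5;45.0
12,right,1,R1,0.7,0.0,0.7,20.5
13,right,1,R2;R3,2.9,0.5,2.6,75.8;63.4
14,right,1,R3,0.9,0.9,1.2,24.0
14,right,2,R1;R2,0.7,3.6,1.3,86.9;52.4
14,left,1,L2,0.2,0.5,0.7,19.6
14,left,2,L2,1.6,0.2,0.7,65.2
15,right,1,R2;R3,0.1,0.2,1.1,31.5;39.9
16,right,1,R1;R2,0.4,0.7,0.7,120.1;66.9
16,right,2,R1;R2,1.2,0.3,0.8,132.2;85.4
16,right,3,R3,0.4,1.3,1.4,44.2
16,right,4,R1;R2,1.3,0.1,0.8,146.0;49.5
16,left,1,L1,1.7,2.3,1.4,43.3
17,right,1,R2,0.2,4.4,1.2,92.0
17,right,2,R1,0.5,1.8,0.8,81.2
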