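patient_id,gtv_right,gtv_left,gtv_total,fm_right,fm_left,fm_total,n_plans,n_log_plans
1,6,3,9,3,2,5,9,8
2,1,0,1,3,0,3,1,1
3,0,2,2,3,2,5,2,2
4,0,1,1,3,2,5,1,1
5,1,0,1,2,2,4,1,1
6,4,0,4,3,3,6,4,3
7,1,0,1,2,1,3,0,0
8,3,1,4,2,1,3,4,3
9,2,0,2,2,2,4,2,2
10,1,0,1,1,1,2,1,0
11,1,1,2,2,2,4,2,2
12,1,0,1,3,0,3,1,1
13,1,0,1,3,2,5,1,1
14,2,2,4,3,3,6,4,4
15,1,0,1,3,2,5,1,1
16,4,1,5,3,2,5,5,1
17,2,0,2,3,2,5,2,0
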