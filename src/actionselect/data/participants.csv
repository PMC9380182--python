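subject_id,sex,age,months_post_stroke,lesion_side,lesion_volume_cc,cst_fa_ratio,tulia,ue_fm,bbt_more,bbt_less,sis_hand
1,M,54,64,L,187.4,1.0,229,54,37,48,50
2,M,67,158,L,113.2,0.96,238,51,50,51,60
3,F,63,49,L,3.1,0.93,240,47,22,34,45
4,M,65,113,L,67.7,0.88,221,47,33,49,35
5,M,59,25,R,1.7,0.84,235,20,3,45,5
6,M,61,41,L,0.2,0.84,224,26,13,42,15
7,M,40,53,R,23.0,0.92,236,61,48,51,95
8,M,56,13,R,15.0,0.76,237,24,8,53,50
9,M,47,11,R,3.3,0.88,237,21,4,68,5
10,M,61,12,L,0.2,1.1,232,52,44,50,100
11,M,57,6,L,1.6,0.89,234,36,28,46,30
12,F,53,13,R,30.0,0.94,217,43,23,31,15
13,F,60,7,R,3.7,0.99,231,59,44,48,75
14,F,35,41,L,0.8,0.88,240,59,16,51,45
15,F,64,12,R,16.3,0.84,231,54,36,44,70
16,M,56,22,L,1.0,0.78,236,18,2,45,15
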