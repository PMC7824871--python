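participant,tfi_total,tsns_overall,dass_depression,dass_anxiety,dass_stress,panas_positive,panas_negative
1,43.6,3,1,1,3,34,13
2,15.6,3,0,0,1,42,12
3,30.4,3,0,1,1,43,14
4,58.8,2,2,16,15,39,17
5,100,5,37,15,26,31,35
6,41.2,3,11,1,14,31,15
7,26.8,3,2,5,11,40,27
8,13.6,2,0,1,1,20,15
9,12.8,2,0,1,2,50,10
10,23.2,2,0,2,1,44,15
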