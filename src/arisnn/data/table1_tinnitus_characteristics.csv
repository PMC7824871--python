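participant,duration_yrs,pitch_hz,level_db,c_mml_db,am_mml_db
1,9,6951,71,37.6,37.7
2,14,2436,70,64.9,59.1
3,9,2420,60,79.9,74.4
4,10,5340,28,58.3,42
5,7,6649,82,67.7,65.9
6,3,5034,80,67.7,65.4
7,13,7151,80,83.1,74.4
8,5,5021,36,36,33.1
9,40,5500,88,73.5,71.7
10,12,1174,68,90.8,90.5
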