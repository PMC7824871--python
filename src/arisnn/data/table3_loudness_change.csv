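participant,constant_change,am_change,ari_group
1,0,0,Non-responder
2,0,0,Non-responder
3,-4,-5,Responder
4,-1,-1,Responder
5,3,0,Non-responder
6,-2,-3,Responder
7,-4,-3,Responder
8,-2,-2,Responder
9,1,1,Non-responder
10,-2,-2,Responder
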