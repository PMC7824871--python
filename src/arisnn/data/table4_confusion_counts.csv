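condition,actual_class,pred_responder,pred_nonresponder
AM,responder,118,2
AM,nonresponder,2,58
C,responder,118,2
C,nonresponder,10,50
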