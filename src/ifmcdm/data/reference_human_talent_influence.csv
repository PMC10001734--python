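element,D,R,prominence,relation,role
SH19,16.532,16.394,32.926,0.138,dispatcher
SH20,17.222,16.377,33.599,0.844,dispatcher
SH21,15.898,16.973,32.871,-1.075,receiver
SH22,16.256,16.164,32.420,0.093,dispatcher
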