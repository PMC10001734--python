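row,col,mu,nu
SH6,SH6,0.020,0.180
SH6,SH7,0.105,0.195
SH6,SH8,0.123,0.209
SH7,SH6,0.132,0.172
SH7,SH7,0.020,0.180
SH7,SH8,0.100,0.206
SH8,SH6,0.174,0.163
SH8,SH7,0.114,0.188
SH8,SH8,0.020,0.180
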