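element,mu,nu,overall_weight
SH6,0.083,0.195,0.291
SH7,0.084,0.186,0.312
SH8,0.103,0.177,0.396
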