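element,SH19,SH20,SH21,SH22
SH19,0.000,3.600,3.100,3.600
SH20,3.100,0.000,3.600,3.100
SH21,3.100,3.600,0.000,2.100
SH22,3.600,2.100,3.600,0.000
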