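element,SH19,SH20,SH21,SH22
SH19,0.0,3.016666666666667,2.85,2.9333333333333336
SH20,3.1833333333333336,0.0,3.35,2.766666666666667
SH21,2.6833333333333336,2.8333333333333335,0.0,2.85
SH22,2.85,2.85,2.9166666666666665,0.0
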