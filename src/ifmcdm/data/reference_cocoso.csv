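alternative,S,P,Ma,Mb,Mc,M,rank
D1,0.74,27.89,0.350,2.605,0.933,2.243,2
D2,0.78,29.91,0.375,2.783,1.000,2.401,1
D3,0.55,21.91,0.275,2.000,0.732,1.740,3
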