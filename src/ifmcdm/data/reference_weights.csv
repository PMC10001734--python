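element,parent,local,overall
H1,,0.144,0.144
H2,,0.119,0.119
H3,,0.117,0.117
H4,,0.134,0.134
H5,,0.137,0.137
H6,,0.109,0.109
H7,,0.123,0.123
H8,,0.119,0.119
SH1,H1,0.197,0.028
SH2,H1,0.202,0.029
SH3,H1,0.220,0.032
SH4,H1,0.179,0.026
SH5,H1,0.201,0.029
SH6,H2,0.316,0.038
SH7,H2,0.326,0.039
SH8,H2,0.358,0.043
SH9,H3,0.333,0.039
SH10,H3,0.333,0.039
SH11,H3,0.333,0.039
SH12,H4,0.140,0.019
SH13,H4,0.148,0.020
SH14,H4,0.121,0.016
SH15,H4,0.143,0.019
SH16,H4,0.140,0.019
SH17,H4,0.141,0.019
SH18,H4,0.168,0.022
SH19,H5,0.214,0.029
SH20,H5,0.259,0.035
SH21,H5,0.267,0.037
SH22,H5,0.260,0.036
SH23,H6,0.228,0.025
SH24,H6,0.256,0.028
SH25,H6,0.231,0.025
SH26,H6,0.286,0.031
SH27,H7,0.198,0.024
SH28,H7,0.208,0.026
SH29,H7,0.201,0.025
SH30,H7,0.200,0.025
SH31,H7,0.193,0.024
SH32,H8,0.239,0.028
SH33,H8,0.244,0.029
SH34,H8,0.266,0.032
SH35,H8,0.251,0.030
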