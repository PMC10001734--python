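subcriterion,D1,D2,D3,weight,direction
SH1,80.0,100.0,90.0,0.028,benefit
SH2,0.0,0.0,0.0,0.029,cost
SH3,1.0,1.0,1.0,0.032,benefit
SH4,1.0,1.0,1.0,0.026,benefit
SH5,2200.0,2800.0,3000.0,0.029,benefit
SH6,100.0,100.0,95.0,0.038,benefit
SH7,98.0,95.0,95.0,0.039,benefit
SH8,0.0,0.5,1.0,0.043,cost
SH9,1.0,1.0,1.0,0.039,benefit
SH10,99.0,100.0,95.0,0.039,benefit
SH11,0.0,0.0,0.0,0.039,benefit
SH12,90.0,60.0,120.0,0.019,cost
SH13,90.0,60.0,60.0,0.02,cost
SH14,15.0,15.0,20.0,0.016,cost
SH15,5.0,60.0,5.0,0.019,cost
SH16,1.0,1.0,1.0,0.019,benefit
SH17,1.0,1.0,1.0,0.019,benefit
SH18,0.0,0.0,0.0,0.022,benefit
SH19,6.0,3.0,8.0,0.029,cost
SH20,30.0,4.0,36.0,0.035,cost
SH21,60.0,80.0,90.0,0.037,benefit
SH22,26.0,23.0,20.0,0.036,cost
SH23,68.0,85.0,100.0,0.025,cost
SH24,95.0,95.0,90.0,0.028,benefit
SH25,90.0,95.0,90.0,0.025,benefit
SH26,40.0,90.0,70.0,0.031,cost
SH27,5.0,5.0,7.0,0.024,cost
SH28,85.0,91.0,90.0,0.026,benefit
SH29,60.0,60.0,65.0,0.025,cost
SH30,0.1,1.0,0.5,0.025,cost
SH31,5.0,5.0,5.0,0.024,cost
SH32,0.0,0.0,0.0,0.028,cost
SH33,0.0,0.0,0.0,0.029,cost
SH34,0.0,0.0,0.0,0.032,cost
SH35,0.0,0.002,0.001,0.03,cost
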