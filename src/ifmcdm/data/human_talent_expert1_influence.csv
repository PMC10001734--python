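row,col,label
SH19,SH20,very high influence
SH19,SH21,high influence
SH19,SH22,very high influence
SH20,SH19,high influence
SH20,SH21,medium influence
SH20,SH22,high influence
SH21,SH19,high influence
SH21,SH20,very high influence
SH21,SH22,medium influence
SH22,SH19,very high influence
SH22,SH20,medium influence
SH22,SH21,low influence
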