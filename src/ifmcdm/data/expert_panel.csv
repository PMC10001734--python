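expert_id,importance_label
DM1,very relevant
DM2,very relevant
DM3,very relevant
DM4,very relevant
DM5,very relevant
DM6,relevant
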