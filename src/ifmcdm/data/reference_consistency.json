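{"criteria": 0.058, "H1": 0.046, "H2": 0.024, "H3": 0.003, "H4": 0.046,
 "H5": 0.062, "H6": 0.057, "H7": 0.097, "H8": 0.020}
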