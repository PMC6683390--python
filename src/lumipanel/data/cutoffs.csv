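bead_id,neg_mean,neg_sd,cutoff,n_controls
GPIaIIa,,,132.29,
GPIbaIX,,,85.19,
HLA,,,131.97,
GPIIbIIIa,,,163.46,
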