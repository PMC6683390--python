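sample_id,call
S2,Anti-HLA + anti-HPA-2b
S3,Anti-HLA + anti-HPA-5b
T5,Anti-HPA-1a
S7,Anti-HPA-5a + anti-HPA-1a
T8,Anti-HLA + anti-HPA-3a
S9,Anti-HLA + anti-HPA-3b
T10,Anti-HPA-5b
S11,Anti-HPA-1a
S12,Anti-HLA
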