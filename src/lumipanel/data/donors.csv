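donor_id,HPA-1,HPA-2,HPA-3,HPA-4,HPA-5,HPA-15
G1,aa,ab,ab,aa,aa,ab
G2,aa,ab,aa,aa,aa,bb
G3,aa,aa,bb,aa,aa,aa
G4,aa,aa,ab,aa,ab,bb
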