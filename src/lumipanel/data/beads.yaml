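# Default bead panel: capture monoclonals and the HPA systems resident on
# each target glycoprotein.  The CD109 bead is defined but disabled: CD109
# capture does not reliably report HPA-15 reactivity, so it is opt-in.
beads:
  - id: GPIaIIa
    code: LC10020-01
    target: GPIa/IIa
    systems: [HPA-5]
    role: hpa_capture
    enabled: true
  - id: GPIbaIX
    code: LC10036-01
    target: GPIba/IX
    systems: [HPA-2]
    role: hpa_capture
    enabled: true
  - id: HLA
    code: LC10050-01
    target: HLA-I
    systems: []
    role: hla_capture
    enabled: true
  - id: GPIIbIIIa
    code: LC10066-01
    target: GPIIb/IIIa
    systems: [HPA-1, HPA-3, HPA-4]
    role: hpa_capture
    enabled: true
  - id: CD109
    code: LC10046-01
    target: CD109
    systems: [HPA-15]
    role: hpa_capture
    enabled: false
  - id: IgG
    code: LC10086-01
    target: IgG-control
    systems: []
    role: positive_control
    enabled: true
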