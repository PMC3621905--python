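name: Kdr
gating:
  kind: gateset
  gates:
  - name: kdr_n
    states:
    - name: C
      role: closed
    - name: O
      role: open
    conducting:
    - O
    transitions:
    - from: C
      to: O
      k0: 1.92
      a: 0.07
    - from: O
      to: C
      k0: 0.239
      a: -0.0133
    multiplicity: 4
gmax: 0.00018
gmax_units: S_per_cm2
erev_mV: -91.5
provenance: delayed-rectifier potassium channel (n^4), granule-cell class
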