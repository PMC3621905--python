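name: Ca
gating:
  kind: gateset
  gates:
  - name: ca_m
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
      k0: 4.17
      a: 0.0714
    - from: O
      to: C
      k0: 0.24
      a: -0.0714
    multiplicity: 2
gmax: 6.0e-07
gmax_units: S_per_cm2
erev_mV: 80.0
provenance: high-voltage-activated calcium channel (m^2), granule-cell class
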