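name: Na
gating:
  kind: gateset
  gates:
  - name: na_m
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
      k0: 114.3
      a: 0.14
    - from: O
      to: C
      k0: 4.82
      a: -0.0267
    multiplicity: 3
  - name: na_h
    states:
    - name: O
      role: open
    - name: C
      role: closed
    conducting:
    - O
    transitions:
    - from: C
      to: O
      k0: 0.00066
      a: -0.1467
    - from: O
      to: C
      k0: 1.005
      a: 0.02
    multiplicity: 1
gmax: 0.1
gmax_units: S_per_cm2
erev_mV: 60.0
provenance: transient sodium channel; granule-cell class HH kinetics recast as single-barrier gates
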