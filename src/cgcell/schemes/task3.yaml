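name: TASK3
gating:
  kind: gateset
  gates:
  - name: k2p_vgate
    states:
    - name: C
      role: closed
    - name: O
      role: open
    - name: O2
      role: open
    conducting:
    - O
    - O2
    transitions:
    - from: C
      to: O
      k0: 0.05235276325186
      a: 0.0011111111111111111
    - from: O
      to: C
      k0: 1.0
      a: -0.0011111111111111111
    - from: O
      to: O2
      k0: 0.9097959895689501
      a: 0.05
    - from: O2
      to: O
      k0: 2.0247882113640046
      a: -0.03
    multiplicity: 1
  - name: task3_mgate
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
      k0: 2.0
      a: 0.0005
    - from: O
      to: C
      k0: 0.06
      a: -0.0005
    multiplicity: 1
gmax: 30.0
gmax_units: nS
erev_mV: -91.5
provenance: two-pore-domain acid-sensitive potassium channel; two independent gates, both must be open
  to conduct
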