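name: K2P
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
  - name: k2p_mgate
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
      k0: 4.0
      a: 0.002
    - from: O
      to: C
      k0: 33.89040070126843
      a: -0.002
    multiplicity: 1
gmax: 60.0
gmax_units: nS
erev_mV: -91.5
provenance: DPP6-insensitive residual two-pore-domain potassium channel; TASK-3 gate pair with a faster,
  more voltage-dependent modulatory gate
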