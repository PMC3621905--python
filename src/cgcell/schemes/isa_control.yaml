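name: ISA_control
gating:
  kind: markov
  name: ISA_control
  states:
  - name: C1
    role: closed
  - name: C2
    role: closed
  - name: O
    role: open
  - name: IN
    role: inactivated
  - name: I1
    role: inactivated
  - name: I2
    role: inactivated
  - name: I3
    role: inactivated
  conducting:
  - O
  transitions:
  - from: C1
    to: C2
    k0: 2.5
    a: 0.06
  - from: C2
    to: C1
    k0: 0.0503
    a: -0.04
  - from: C2
    to: O
    k0: 3.0
    a: 0.04
  - from: O
    to: C2
    k0: 0.217
    a: -0.03
  - from: C2
    to: I2
    k0: 0.067
    a: 0.03
  - from: I2
    to: C2
    k0: 8.7e-05
    a: -0.05
  - from: O
    to: IN
    k0: 0.06
    a: 0.005
  - from: IN
    to: O
    k0: 0.004
    a: -0.02
  - from: I2
    to: I3
    k0: 0.01
    a: 0.0
  - from: I3
    to: I2
    k0: 0.01
    a: 0.0
  - from: C1
    to: I1
    k0: 1.950449463474987
    a: 0.06
  - from: I1
    to: C1
    k0: 0.00011970834993431687
    a: -0.06
  - from: I1
    to: I2
    k0: 0.05
    a: 0.005
  - from: I2
    to: I1
    k0: 0.02128397245820171
    a: -0.055
gmax: 30.0
gmax_units: nS
erev_mV: -91.5
provenance: somatodendritic A-type potassium channel, control condition (fast kinetics; N-type open-state
  inactivation plus a deep closed-inactivated state)
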