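name: ISA_rnai
gating:
  kind: markov
  name: ISA_rnai
  states:
  - name: C1
    role: closed
  - name: C2
    role: closed
  - name: O
    role: open
  - name: I1
    role: inactivated
  - name: I2
    role: inactivated
  conducting:
  - O
  transitions:
  - from: C1
    to: C2
    k0: 1.0
    a: 0.06
  - from: C2
    to: C1
    k0: 0.149
    a: -0.04
  - from: C2
    to: O
    k0: 1.2
    a: 0.04
  - from: O
    to: C2
    k0: 0.353
    a: -0.03
  - from: C2
    to: I2
    k0: 0.3
    a: 0.03
  - from: I2
    to: C2
    k0: 6.2e-05
    a: -0.05
  - from: C1
    to: I1
    k0: 0.09247394377522969
    a: 0.06
  - from: I1
    to: C1
    k0: 2.5259830281406748e-05
    a: -0.06
  - from: I1
    to: I2
    k0: 0.02
    a: 0.005
  - from: I2
    to: I1
    k0: 0.002254631914462719
    a: -0.055
gmax: 6.0
gmax_units: nS
erev_mV: -91.5
provenance: residual A-type potassium channel after DPP6 knockdown (slow kinetics; inactivation only through
  closed states)
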