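name: KCa
gating:
  kind: calcium_gated
  alpha_per_uM_ms: 2.5
  beta_ms: 1.5
gmax: 0.0015
gmax_units: S_per_cm2
erev_mV: -91.5
provenance: calcium-activated potassium channel driven by a submembrane calcium shell
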