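name: leak_Na
gating:
  kind: ohmic
gmax: 0.133
gmax_units: nS
erev_mV: 60.0
provenance: sodium-selective linear leak; 0.133 nS
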