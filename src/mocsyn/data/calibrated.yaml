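channels:
  densities:
    klt:
      all: 0.000285
    hcn:
      all: 2.6261698909867522e-05
    leak:
      all: 5.844055858866436e-05
    na:
      all: 0.0213
      axon: 0.213
    kht:
      all: 0.00141
      axon: 0.0141
  e_k: -90.0
  e_na: 55.0
  e_h: -38.0
  e_leak: -65.0
  klt_rate_per_ms: 0.6
  gate_q10: 1.0
  rate_base_c: 22.0
minis:
  epsp:
    tau_rise: 0.2
    tau_decay: 11.807528425727055
    weight: 0.0002396040637368645
    reversal: 0.0
  ipsp:
    tau_rise: 2.75
    tau_decay: 22.234921150174834
    weight: 0.0005696045056611211
    reversal: -90.0
holding:
  target_mV: -60.0
provenance: produced by analysis/04_calibrate_model.py; see docs/methods.md
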