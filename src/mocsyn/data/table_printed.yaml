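# Channel table as printed in the source publication, verbatim including
# its unit anomalies (cS/cm^2, kS/cm^2, nS/cm^2 are typesetting artifacts).
# These values are archived for reference; the working model densities are
# the calibrated ones in calibrated.yaml (see docs/methods.md).
channels:
  - {name: "High threshold K+ (h.HT)", location: "All",  conductance: "0.02 S/cm^2"}
  - {name: "Low threshold K+ (h.LT)",  location: "All",  conductance: "12 mS/cm^2"}
  - {name: "Low threshold K+ (h.kbl_LT)", location: "All", conductance: "0.6 ms^-1"}
  - {name: "H-H type Na+ (h.na)",      location: "All",  conductance: "8 nS/cm^2"}
  - {name: "HCN (h.Ih_400t8)",         location: "All",  conductance: "12 uS/cm^2"}
  - {name: "High threshold K+ (h.HT)", location: "Axon", conductance: "0.32 mS/cm^2"}
  - {name: "Low threshold K+ (h.LT)",  location: "Axon", conductance: "6 cS/cm^2"}
  - {name: "H-H type Na+ (h.na)",      location: "Axon", conductance: "9 kS/cm^2"}
hcn_reversal_mV: -38.0
axial_resistivity_ohm_cm: 210.0
membrane_capacitance_uF_cm2: 1.0
temperature_C: 35.0
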