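{
  "_comment": "Channel decoration tables for bushy-cell models. somatic_base_nS are whole-cell conductances of the reference somatic model at 37 degC; axon_ratios are densities relative to the somatic density; dendrite_modes give relative densities for Na/KHT/KLT/IH and absolute leak density in mS/cm^2.",
  "somatic_base_nS": {"Na": 500.0, "KHT": 58.0, "KLT": 80.0, "IH": 30.0},
  "somatic_leak_mS_cm2": 0.1385,
  "axon_ratios": {
    "myelinated": {"Na": 0.0, "KHT": 0.01, "KLT": 0.01, "IH": 0.0, "Leak": 0.00025},
    "AIS": {"Na": 100.0, "KHT": 2.0, "KLT": 1.0, "IH": 0.5, "Leak": 1.0},
    "hillock": {"Na": 5.0, "KHT": 1.0, "KLT": 1.0, "IH": 0.0, "Leak": 1.0}
  },
  "dendrite_modes": {
    "passive": {"Na": 0.0, "KHT": 0.0, "KLT": 0.0, "IH": 0.0, "Leak": 0.0693},
    "half_active": {"Na": 0.5, "KHT": 0.5, "KLT": 0.5, "IH": 0.5, "Leak": 0.0693},
    "active": {"Na": 1.0, "KHT": 1.0, "KLT": 1.0, "IH": 1.0, "Leak": 0.1385}
  }
}
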