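{
  "pressure_optics": {
    "intercept_a": 0.0,
    "slope_b": 2.15
  },
  "flow_optics": {
    "m_prime": 1613.0,
    "q_c": 328.0,
    "tau_d": 0.39,
    "tau_a": 1.78,
    "nd_na_ratio": 2.2,
    "gamma_c": 870.0
  },
  "sensor": {
    "response_coefficient_c": 1.0,
    "response_exponent_d": 1.3,
    "wavelength": 830.0,
    "dc_offset": 0.0
  },
  "vessel": {
    "reference_diameter": 4.0,
    "reference_pressure": 100.0,
    "pd_slope_b": 0.001245,
    "is_stiff": false,
    "length_segment": 50.0
  }
}
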