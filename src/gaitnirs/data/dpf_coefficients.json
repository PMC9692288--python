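{
  "description": "Coefficients of the general differential-pathlength-factor equation DPF(lambda, age) = alpha + beta*age^gamma + delta*lambda^3 + epsilon*lambda^2 + zeta*lambda, with age in years and lambda in nm (Scholkmann & Wolf 2013, J Biomed Opt 18:105004).",
  "alpha": 223.3,
  "beta": 0.05624,
  "gamma": 0.8493,
  "delta": -5.723e-07,
  "epsilon": 0.001245,
  "zeta": -0.9025,
  "age_range_years": [0, 100],
  "wavelength_range_nm": [690, 900]
}
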