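# EUD/NTCP parameter registry for the phenomenological (Niemierko-style)
# model.  Values are photon-derived literature defaults commonly used with
# the EUD-based logistic NTCP (volume-effect exponent a, alpha/beta in Gy,
# TD50 in Gy EQD2, unitless gamma50); they are configuration, not measured
# constants, and can be overridden per run.
total_lung:
  endpoint: pneumonitis
  a: 1.0
  alpha_beta_gy: 3.0
  td50_gy: 24.5
  gamma50: 2.0
heart:
  endpoint: pericarditis
  a: 3.0
  alpha_beta_gy: 3.0
  td50_gy: 48.0
  gamma50: 3.0
esophagus:
  endpoint: esophagitis
  a: 19.0
  alpha_beta_gy: 10.0
  td50_gy: 68.0
  gamma50: 4.0
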