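# Temperature functionals, Model 2 variant (SYNTHETIC defaults).
# The overall scale alpha carries most of the tuning; see
# tempfuncs_model3_synthetic.yaml.
provenance: synthetic
model: 2
Tref: 298.15
functionals:
  A: {a: 1.1e-6, b: 4.8e-4, c: 0.0, alpha: 1.6}
  V: {a: 1.2e-6, b: 5.4e-4, c: 0.0, alpha: 1.6}
  I: {a: 1.3e-6, b: 6.0e-4, c: 0.0, alpha: 1.6}
  L: {a: 1.3e-6, b: 6.0e-4, c: 0.0, alpha: 1.6}
  M: {a: 1.4e-6, b: 6.6e-4, c: 0.0, alpha: 1.6}
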