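# Temperature functionals, Model 1 variant (SYNTHETIC defaults).
# Both the parabola and alpha are tuned; see tempfuncs_model3_synthetic.yaml.
provenance: synthetic
model: 1
Tref: 298.15
functionals:
  A: {a: 2.5e-6, b: 1.1e-3, c: 0.0, alpha: 0.8}
  V: {a: 2.8e-6, b: 1.3e-3, c: 0.0, alpha: 0.8}
  I: {a: 3.1e-6, b: 1.4e-3, c: 0.0, alpha: 0.8}
  L: {a: 3.1e-6, b: 1.4e-3, c: 0.0, alpha: 0.8}
  M: {a: 3.4e-6, b: 1.5e-3, c: 0.0, alpha: 0.8}
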