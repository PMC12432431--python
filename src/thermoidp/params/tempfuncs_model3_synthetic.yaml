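# Temperature functionals for hydrophobic residues (SYNTHETIC defaults).
#
# mu_X(T) = a T^2 + b T + c (kcal/mol, T in K); the pair well depth for any
# pair containing a hydrophobic residue is shifted by alpha*(mu(T)-mu(Tref)).
# Model 3 variant: the parabolic term carries the tuning, alpha = 1.
# Coefficients are SYNTHETIC placeholders producing a mild strengthening of
# hydrophobic attraction with temperature (LCST-type behavior); replace with
# a published set for full-fidelity work.
provenance: synthetic
model: 3
Tref: 298.15
functionals:
  A: {a: 1.8e-6, b: 8.0e-4, c: 0.0, alpha: 1.0}
  V: {a: 2.0e-6, b: 9.0e-4, c: 0.0, alpha: 1.0}
  I: {a: 2.2e-6, b: 1.0e-3, c: 0.0, alpha: 1.0}
  L: {a: 2.2e-6, b: 1.0e-3, c: 0.0, alpha: 1.0}
  M: {a: 2.4e-6, b: 1.1e-3, c: 0.0, alpha: 1.0}
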