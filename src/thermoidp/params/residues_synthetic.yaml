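# Residue bead table (synthetic defaults).
#
# Masses are standard average residue masses (amu) and charges follow the
# usual residue-level convention at pH ~ 7.4 (D/E = -1, K/R = +1, H set by
# `histidine_charge`).  Bead diameters are the van-der-Waals residue
# diameters commonly used by residue-level coarse-grained protein models.
# The homotypic well depths `eps_homotypic` (kcal/mol) are SYNTHETIC
# placeholder values chosen to be physically plausible (aromatics
# stickiest, small polar residues weakest); replace this file with a
# published parameter set for full-fidelity work.
provenance: synthetic
histidine_charge: 0.0
bond:
  k: 4000.0    # kcal/mol/nm^2 in U = 0.5 k (r - r0)^2
  r0: 0.381    # nm
wang_frenkel:
  mu: 1.0
  nu: 1.0
yukawa_cutoff_nm: 3.5
residues:
  A: {mass: 71.0788,  charge: 0.0,  sigma: 0.504, eps_homotypic: 0.30}
  R: {mass: 156.1875, charge: 1.0,  sigma: 0.656, eps_homotypic: 0.45}
  N: {mass: 114.1038, charge: 0.0,  sigma: 0.568, eps_homotypic: 0.35}
  D: {mass: 115.0886, charge: -1.0, sigma: 0.558, eps_homotypic: 0.25}
  C: {mass: 103.1388, charge: 0.0,  sigma: 0.548, eps_homotypic: 0.35}
  Q: {mass: 128.1307, charge: 0.0,  sigma: 0.602, eps_homotypic: 0.38}
  E: {mass: 129.1155, charge: -1.0, sigma: 0.592, eps_homotypic: 0.25}
  G: {mass: 57.0519,  charge: 0.0,  sigma: 0.450, eps_homotypic: 0.25}
  H: {mass: 137.1411, charge: 0.0,  sigma: 0.608, eps_homotypic: 0.42}
  I: {mass: 113.1594, charge: 0.0,  sigma: 0.618, eps_homotypic: 0.37}
  L: {mass: 113.1594, charge: 0.0,  sigma: 0.618, eps_homotypic: 0.37}
  K: {mass: 128.1741, charge: 1.0,  sigma: 0.636, eps_homotypic: 0.25}
  M: {mass: 131.1926, charge: 0.0,  sigma: 0.618, eps_homotypic: 0.40}
  F: {mass: 147.1766, charge: 0.0,  sigma: 0.636, eps_homotypic: 0.60}
  P: {mass: 97.1167,  charge: 0.0,  sigma: 0.556, eps_homotypic: 0.30}
  S: {mass: 87.0782,  charge: 0.0,  sigma: 0.518, eps_homotypic: 0.28}
  T: {mass: 101.1051, charge: 0.0,  sigma: 0.562, eps_homotypic: 0.30}
  W: {mass: 186.2132, charge: 0.0,  sigma: 0.678, eps_homotypic: 0.75}
  Y: {mass: 163.1760, charge: 0.0,  sigma: 0.646, eps_homotypic: 0.65}
  V: {mass: 99.1326,  charge: 0.0,  sigma: 0.586, eps_homotypic: 0.33}
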