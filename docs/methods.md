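# Methods

`thermoidp` implements a residue-resolution, implicit-solvent coarse-grained
model for the temperature-dependent phase behavior of intrinsically
disordered proteins (IDPs), together with the analysis machinery needed to
extract cloud points, coil-to-globule transitions and binodals from
simulations. This note records the model, its assumptions, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## The model

Each amino acid is one spherical bead carrying a mass, a charge, a diameter
σ and interaction parameters. The potential energy has three terms:

1. **Bonds.** Consecutive residues interact through a harmonic potential
   U = ½ k (r − r₀)², defaults k = 4000 kcal mol⁻¹ nm⁻² and r₀ = 0.381 nm
   (the Cα–Cα virtual bond length). Both are fields of the residue table.

2. **Short-range nonbonded: Wang–Frenkel.** The canonical form

       φ(r) = ε α [(σ/r)^{2μ} − 1] [(R/r)^{2μ} − 1]^{2ν},   R = 3σ,

   vanishes identically at its cutoff and, with the normalizer
   α(σ,R,μ,ν) = 2ν(R/σ)^{2μ} [(2ν+1)/(2ν((R/σ)^{2μ}−1))]^{2ν+1}, has a
   minimum of exactly −ε at the interior stationary point
   r* = R[(1+2ν)/(1+2ν(R/σ)^{2μ})]^{1/(2μ)}. Temperature scaling can push a
   pair's well depth negative; the canonical form would then be attractive
   at contact, so a revised branch is used for ε < 0:

       φ_rep(r) = −φ_WF(r) − ε   (r < r*),   0   (r ≥ r*).

   This branch is continuous at r*, non-negative, divergent at r → 0, and
   keeps the bead diameter of the canonical potential. Shape exponents
   default to μ = ν = 1 and are config fields.

3. **Electrostatics: temperature-scaled Yukawa.** Charged beads interact
   through φ = (q_i q_j e²/4πε₀ε(T))·exp(−κ(T)r)/r with plain truncation
   (default 3.5 nm, clamped to half the smallest box edge). Two analytic
   temperature dependencies enter:

   * the dielectric constant ε(T) = 1 + ρ_w(T)·d(T), with ρ_w(T) the Kell
     (1975) rational polynomial for air-free water at 1 atm and d(T) linear
     in T. The shipped (d₀, d₁) were obtained by a minimax fit of ε(T) to
     the Malmberg–Maryott tabulated static permittivity of water on
     273.15–373.15 K (max deviation 1.5%; an ordinary least-squares fit of
     the same form leaves 2.2%, outside the 2% agreement this package
     promises, which is why the minimax criterion was used);
   * the inverse Debye length κ² = e²/(ε(T)ε₀k_BT)·Σ z_j²n_j, with the
     self-consistent ε(T) and ion number densities from the configured
     molar concentrations (default 150 mM 1:1 salt). Temperature queries
     outside 273.15–373.15 K raise errors rather than extrapolate: the
     model is defined for liquid water only.

### Temperature-dependent well depths

The heart of the model is the scaling of pair well depths. Hydrophobic
residues (A, V, I, L, M) drive heating-induced (LCST-type) demixing: the
entropic penalty of hydration water around nonpolar side chains grows with
temperature, which an implicit-solvent model must fold into its effective
pair energies. For any pair containing at least one hydrophobic residue,

    ε_ij(T) = ½[ε_ii + α_i(μ_i(T) − μ_i(T_ref))] + ½[ε_jj + α_j(μ_j(T) − μ_j(T_ref))],

with parabolic per-residue functionals μ_X(T) = a_X T² + b_X T + c_X
anchored at T_ref = 298.15 K (the constant c cancels but is kept as a
field). Pairs with no hydrophobic member keep their baseline value at every
temperature: the temperature dependence of charged residues is already in
the electrostatics, and association between polar/aromatic pairs weakens
with T through ordinary kinetics that the baseline model is assumed to
capture. At T_ref every scaled pair reduces exactly to the arithmetic mean
of the two homotypic well depths — this anchor is asserted over all 400
ordered pairs in the tests.

Three functional-form variants are shipped (model 1: both α and the
parabola tuned; model 2: α-dominant; model 3: parabola-dominant, α = 1,
the recommended default).

**Parameter provenance.** The bundled residue table and temperature
functionals are *synthetic stand-ins*, clearly labelled as such in the
YAML files: masses and charges are the standard residue values (D/E = −1,
K/R = +1, histidine charge a config field defaulting to 0), σ are the
common residue-level CG diameters, but homotypic well depths and (a,b,c,α)
are physically plausible placeholder values chosen once — aromatics
stickiest, hydrophobic attraction mildly strengthening on heating
(~+0.14 kcal/mol from 298 to 360 K for the V–V pair under model 3). All of
the machinery is parameter-file-driven, so a published set drops in without
code changes.

## The engine

A desk-scale NVT Langevin sampler: BAOAB splitting, default timestep 10 fs,
thermostat relaxation time 5 ps, Maxwell–Boltzmann initial velocities,
minimum-image periodic boundaries, Verlet neighbor list (skin 0.3 nm,
displacement-triggered rebuilds, O(N²) chunked construction — adequate for
the few thousand beads this engine targets). With the friction off BAOAB
degenerates to velocity Verlet, which is how the symplectic-drift check is
run (energy drift < 1e-4 relative over 10⁴ steps at 1 fs). Identical seeds
give bitwise-identical trajectories. Internal units: kcal/mol, nm, amu, ps
(1 kcal/mol = 4.184 amu nm² ps⁻²); all conversions to the MD-engine export
convention are centralized in the bridge module.

System builders: `build_single_chain` (seeded self-avoiding walk, no
contact below 0.7σ, box must exceed the chain contour length) and
`build_slab` (64 = 4³ chain replicates below 190 residues, 27 = 3³ at or
above; compact coils packed into a central slab at the requested dense
density in the 0.8–1.0 g/cm³ window, z edge extended so total mass over
box volume equals the target concentration, then a capped steepest-descent
relaxation). An NPT compression stage is deliberately not implemented:
production slabs are expected to run through the exported MD-engine inputs
(50 ns equilibration + 400 ns production at 10 fs, z-density profile every
1 ns), and the internal builder places chains at the dense density
directly.

## Analysis

* **Cloud point from density profiles.** At a fixed (dilute) concentration,
  finite-size effects make a slab's z-density profile develop a sharp
  condensate spike once the state point crosses the dilute arm of the
  binodal. The detector flags a frame when max bin density ≥ 3× the median
  bin density (config `spike_factor`), requires ≥ 2 consecutive flagged
  frames (config `persistence`), and reports the lowest flagged temperature
  of an ascending scan; a spike already present at the lowest scanned
  temperature triggers a boundary warning.
* **Coexistence densities.** The time-averaged profile is rolled so the
  dense slab is centered (condensates split across the periodic boundary
  are handled), split at the midpoint density, and each phase averaged over
  its interior after discarding 10% of its width per side as interfacial
  margin. Profiles with relative contrast below 0.2 are rejected as
  single-phase.
* **Critical point.** Simultaneous unweighted least squares of the law of
  coexistence densities, ρ_dense − ρ_dilute = A|T−T_c|^β, and the law of
  rectilinear diameters, (ρ_dense+ρ_dilute)/2 = ρ_c + s|T−T_c|, with
  β = 0.325 (3D Ising) by default and T_c parameterized as a positive
  offset from the data edge so the LCST branch keeps T > T_c (UCST:
  T < T_c) throughout the optimization.
* **Flory exponent.** For finite heteropolymers the radius of gyration is
  related to an approximate scaling exponent through
  S = √[γ(γ+1)/(2(γ+2ν)(γ+2ν+1))]·b·N^ν with b = 5.5 Å (geometric mean of
  a ~4.0 Å persistence length and the 3.8 Å Cα–Cα distance), γ = 1.1615,
  and N the number of bonds. The relation is monotone in ν, inverted by
  Brent's method on ν ∈ (0.05, 0.95) to 1e-12; out-of-range Rg values are
  rejected with the attainable bounds in the message. The θ temperature is
  the linear interpolation of the first ν = 0.5 crossing of an ascending
  temperature series (the appropriate threshold for finite disordered
  chains, which collapse below the ν = 0.588 of infinite self-avoiding
  homopolymers; multiple crossings are flagged and the lowest returned); the sign
  of the fitted dν/dT classifies a sequence LCST-like (ν falls on heating)
  or UCST-like.
* **Block statistics.** Time series are split into three contiguous equal
  blocks (remainder to the last block); the reported value is the mean of
  block means and the error sd(block means)/√3.
* **Experimental cloud points.** The temperature at which a turbidity
  curve's absorbance first rises through −log₁₀(0.5) = 0.30103
  (transmittance one half), by linear interpolation. Model comparison uses
  the RMSD between paired simulated and experimental cloud points.

## Synthetic data

The generators in `thermoidp.synthetic` define the closed loops that back
the test suite: ELP-like VPGXG repeats; flat noisy z-profiles acquiring a
Gaussian condensate spike at a constructed onset temperature; coexistence
points generated exactly from the two critical laws (plus seeded
multiplicative noise); and Rg(T) tables built from a linear ν(T) ramp
through the finite-chain relation. Every generator is bit-reproducible
under a fixed seed. These fixtures establish that the analysis operators
invert their generating models — they do not establish that the synthetic
force-field parameters reproduce any particular protein's measured cloud
point, which requires the published parameter tables and production-scale
slab simulations through the export path.

## Numerical choices and limitations

* Pair tables for export: 5000 uniform points on (0.01 nm, cutoff];
  linear-interpolation fidelity is verified at export time to 1e-4 kcal/mol
  for r ≥ 0.8σ (inside the hard core the potential reaches ~1e10 kcal/mol
  and an absolute bound on a uniform grid is neither attainable nor
  meaningful).
* Bonded (1–2) pairs are excluded from nonbonded interactions.
* The Yukawa term is plainly truncated (not shifted); the cutoff is a
  config field.
* Problem sizes in the validation suite are desk-scale by design:
  equipartition on a 64-dimer gas, diffusion on a 128-bead free gas,
  ideal-chain scaling on replica ensembles of up to 1600 chains initialized
  from equilibrium random walks. Production phase-diagram work should go
  through the LAMMPS export.
* Not modelled: post-translational modifications, nucleic acids, folded
  domains and their conformational changes, pH titration, explicit
  crowders.
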