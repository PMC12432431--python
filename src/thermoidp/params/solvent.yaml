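# Solvent and electrolyte defaults.
#
# The dielectric constant is eps(T) = 1 + rho_water(T) * d(T) with
# d(T) = d0 + d1*T linear in temperature and rho_water from the Kell (1975)
# rational polynomial.  The (d0, d1) coefficients below were obtained by a
# minimax fit of eps(T) to the Malmberg-Maryott tabulated static
# permittivity of water over 273.15-373.15 K (max deviation 1.5%).
dielectric_d_coeffs: [165.19997698, -0.29206902]   # d0 (cm^3/g), d1 (cm^3/g/K)
temperature_range: [273.15, 373.15]                # K, liquid water
density_model: kell_1975
electrolyte:
  # 1:1 monovalent salt at physiological ionic strength.
  species:
    - {valence: 1, concentration_molar: 0.150}
    - {valence: -1, concentration_molar: 0.150}
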