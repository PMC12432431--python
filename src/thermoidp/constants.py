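"""Physical constants and unit conversions.

Internal unit system: energies in kcal/mol, distances in nm, masses in
atomic mass units (g/mol), time in ps, temperature in K.  In this system
1 kcal/mol = 4.184 amu nm^2 ps^-2, which is the single conversion factor
needed to propagate dynamics.
"""

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # C^2 N^-1 m^-2
BOLTZMANN_J = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

KB_KCAL = 1.987204259e-3  # kcal mol^-1 K^-1
KCAL_TO_INTERNAL = 4.184  # amu nm^2 ps^-2 per kcal/mol

# e^2 / (4 pi eps0) expressed in kcal/mol * nm: the Coulomb energy of two
# elementary charges 1 nm apart in vacuum.
COULOMB_PREFACTOR_KCAL_NM = (
    ELEMENTARY_CHARGE**2
    / (4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY)
    * AVOGADRO
    * 1e9  # m -> nm
    / 4184.0  # J/mol -> kcal/mol
)

FS_TO_PS = 1e-3
NM_TO_ANGSTROM = 10.0
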