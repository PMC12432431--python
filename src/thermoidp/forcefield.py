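"""Temperature-dependent interaction parameters.

This module turns a residue table plus per-residue temperature functionals
into fully resolved pair interaction parameters at a given temperature:

* the static dielectric constant of the implicit solvent,
  ``eps(T) = 1 + rho_water(T) * d(T)`` with a linear solvent parameter
  ``d(T)`` and the Kell (1975) formulation for the density of water;
* the inverse Debye screening length
  ``kappa^2 = e^2 / (eps(T) eps0 kB T) * sum_j z_j^2 c_j``;
* pair well depths ``eps_ij(T)``: pairs containing at least one
  hydrophobic residue (A, V, I, L, M) are scaled as

      eps_ij(T) = 0.5*[eps_ii + alpha_i (mu_i(T) - mu_i(Tref))]
                + 0.5*[eps_jj + alpha_j (mu_j(T) - mu_j(Tref))]

  with parabolic ``mu_X(T) = a T^2 + b T + c`` anchored at
  Tref = 298.15 K, while all other pairs keep their baseline value at
  every temperature.  A scaled well depth may become negative, which
  selects the purely repulsive potential branch downstream.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .constants import (
    AVOGADRO,
    BOLTZMANN_J,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
)
from .sequences import HYDROPHOBIC_RESIDUES, ResidueBead, ResidueTable

TREF = 298.15  # K, reference temperature anchoring the scaling

_KELL_NUMERATOR = (
    999.83952,
    16.945176,
    -7.9870401e-3,
    -46.170461e-6,
    105.56302e-9,
    -280.54253e-12,
)
_KELL_DENOM_B = 16.879850e-3


class TemperatureRangeError(ValueError):
    """Temperature outside the liquid-water validity window."""


def water_density(T, t_range: tuple[float, float] = (273.15, 373.15)):
    """Density of air-free water at 1 atm, g/cm^3 (Kell 1975).

    Rational polynomial in Celsius temperature; valid for liquid water.
    Accepts scalars or arrays.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < t_range[0]) or np.any(T > t_range[1]):
        raise TemperatureRangeError(
            f"temperature outside liquid-water range {t_range} K"
        )
    t = T - 273.15
    num = np.zeros_like(t)
    for k, c in enumerate(_KELL_NUMERATOR):
        num = num + c * t**k
    rho = num / (1.0 + _KELL_DENOM_B * t) / 1000.0
    return rho if rho.ndim else float(rho)


@dataclasses.dataclass(frozen=True)
class SolventModel:
    """Linear solvent parameter d(T) = d0 + d1*T and its validity window."""

    d_coeffs: tuple[float, float]
    t_range: tuple[float, float] = (273.15, 373.15)
    density_model: str = "kell_1975"

    def d(self, T):
        d0, d1 = self.d_coeffs
        return d0 + d1 * np.asarray(T, dtype=float)


def dielectric(T, solvent: SolventModel):
    """Static dielectric constant eps(T) = 1 + rho_water(T) * d(T)."""
    rho = water_density(T, solvent.t_range)
    eps = 1.0 + rho * solvent.d(T)
    return eps if np.ndim(eps) else float(eps)


@dataclasses.dataclass(frozen=True)
class ElectrolyteModel:
    """Ionic species as (valence, molar concentration) pairs."""

    species: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for z, c in self.species:
            if c < 0:
                raise ValueError(f"negative ion concentration {c} mol/L")

    @property
    def ionic_strength(self) -> float:
        return 0.5 * sum(z * z * c for z, c in self.species)


def inverse_debye_length(T: float, electrolyte: ElectrolyteModel, eps: float) -> float:
    """Inverse Debye screening length kappa in nm^-1.

    kappa^2 = e^2 / (eps eps0 kB T) * sum_j z_j^2 n_j with number densities
    n_j converted from the molar concentrations of the electrolyte.
    """
    if eps <= 0:
        raise ValueError("dielectric constant must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    sum_z2n = 0.0  # ions per m^3, weighted by z^2
    for z, c in electrolyte.species:
        sum_z2n += z * z * c * 1000.0 * AVOGADRO
    kappa2 = (
        ELEMENTARY_CHARGE**2
        * sum_z2n
        / (eps * VACUUM_PERMITTIVITY * BOLTZMANN_J * T)
    )  # m^-2
    return float(np.sqrt(kappa2) * 1e-9)  # nm^-1


@dataclasses.dataclass(frozen=True)
class TemperatureFunctional:
    """Parabolic temperature functional mu_X(T) = a T^2 + b T + c.

    ``alpha`` scales the shift ``mu(T) - mu(Tref)`` applied to the
    homotypic well depth of residue ``residue``.
    """

    residue: str
    a: float  # kcal/mol/K^2
    b: float  # kcal/mol/K
    c: float  # kcal/mol
    alpha: float
    tref: float = TREF


def mu(T, f: TemperatureFunctional):
    """Evaluate mu_X(T) = a T^2 + b T + c."""
    T = np.asarray(T, dtype=float)
    val = f.a * T**2 + f.b * T + f.c
    return val if val.ndim else float(val)


def _scaled_half(T: float, bead: ResidueBead, f: TemperatureFunctional | None) -> float:
    if not bead.hydrophobic:
        return 0.5 * bead.eps_homotypic
    if f is None:
        raise KeyError(
            f"hydrophobic residue {bead.code!r} lacks a temperature functional"
        )
    return 0.5 * (bead.eps_homotypic + f.alpha * (mu(T, f) - mu(f.tref, f)))


def epsilon_ij(
    T: float,
    bead_i: ResidueBead,
    bead_j: ResidueBead,
    functionals: dict[str, TemperatureFunctional],
    eps_pair_baseline: float | None = None,
) -> float:
    """Pair well depth eps_ij(T) in kcal/mol (may be negative).

    Pairs with no hydrophobic member return the baseline pair value
    unchanged at every temperature (``eps_pair_baseline`` if supplied,
    otherwise the arithmetic mean of the homotypic well depths).
    """
    if not bead_i.hydrophobic and not bead_j.hydrophobic:
        if eps_pair_baseline is not None:
            return float(eps_pair_baseline)
        return 0.5 * (bead_i.eps_homotypic + bead_j.eps_homotypic)
    return _scaled_half(T, bead_i, functionals.get(bead_i.code)) + _scaled_half(
        T, bead_j, functionals.get(bead_j.code)
    )


class ForceField:
    """A residue table, temperature functionals and solvent/electrolyte models.

    The central object of the model: resolves every temperature-dependent
    interaction parameter needed to simulate or export a system at a given
    temperature.
    """

    def __init__(
        self,
        residues: ResidueTable,
        functionals: dict[str, TemperatureFunctional],
        solvent: SolventModel,
        electrolyte: ElectrolyteModel,
        pair_eps_baseline: dict[frozenset, float] | None = None,
        model_name: str = "custom",
    ) -> None:
        self.residues = residues
        self.functionals = functionals
        self.solvent = solvent
        self.electrolyte = electrolyte
        self.pair_eps_baseline = pair_eps_baseline or {}
        self.model_name = model_name
        missing = [
            code
            for code in HYDROPHOBIC_RESIDUES
            if code in residues.beads and code not in functionals
        ]
        if missing:
            raise KeyError(
                f"hydrophobic residues missing temperature functionals: {sorted(missing)}"
            )

    # -- solvent-level quantities -------------------------------------
    def dielectric(self, T: float) -> float:
        return dielectric(T, self.solvent)

    def kappa(self, T: float) -> float:
        """Inverse Debye length (nm^-1) with the self-consistent eps(T)."""
        return inverse_debye_length(T, self.electrolyte, self.dielectric(T))

    # -- pair-level quantities ----------------------------------------
    def epsilon_ij(self, T: float, code_i: str, code_j: str) -> float:
        base = self.pair_eps_baseline.get(frozenset((code_i, code_j)))
        return epsilon_ij(
            T, self.residues[code_i], self.residues[code_j], self.functionals, base
        )

    def sigma_ij(self, code_i: str, code_j: str) -> float:
        return 0.5 * (self.residues[code_i].sigma + self.residues[code_j].sigma)

    def pair_spec(self, T: float, code_i: str, code_j: str):
        """Fully resolved Wang-Frenkel spec for one pair at one temperature."""
        from .potentials import PairPotentialSpec

        return PairPotentialSpec(
            eps=self.epsilon_ij(T, code_i, code_j),
            sigma=self.sigma_ij(code_i, code_j),
            mu=self.residues.wf_mu,
            nu=self.residues.wf_nu,
        )


def _params_path(name: str) -> Path:
    return Path(str(resources.files("thermoidp").joinpath("params", name)))


def load_functionals(path: str | Path) -> tuple[dict[str, TemperatureFunctional], str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tref = float(raw.get("Tref", TREF))
    funcs = {
        code: TemperatureFunctional(
            residue=code,
            a=float(f["a"]),
            b=float(f["b"]),
            c=float(f["c"]),
            alpha=float(f["alpha"]),
            tref=tref,
        )
        for code, f in raw["functionals"].items()
    }
    return funcs, str(raw.get("model", "custom"))


def load_solvent(path: str | Path | None = None) -> tuple[SolventModel, ElectrolyteModel]:
    if path is None:
        path = _params_path("solvent.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    solvent = SolventModel(
        d_coeffs=tuple(float(x) for x in raw["dielectric_d_coeffs"]),
        t_range=tuple(float(x) for x in raw["temperature_range"]),
        density_model=raw.get("density_model", "kell_1975"),
    )
    electrolyte = ElectrolyteModel(
        species=tuple(
            (float(s["valence"]), float(s["concentration_molar"]))
            for s in raw["electrolyte"]["species"]
        )
    )
    return solvent, electrolyte


def load_forcefield(
    model: int = 3,
    residue_table: str | Path | None = None,
    functional_table: str | Path | None = None,
    solvent_config: str | Path | None = None,
    histidine_charge: float | None = None,
) -> ForceField:
    """Load the bundled (synthetic-default) force field for one model variant."""
    if residue_table is None:
        residue_table = _params_path("residues_synthetic.yaml")
    if functional_table is None:
        functional_table = _params_path(f"tempfuncs_model{model}_synthetic.yaml")
    residues = ResidueTable.from_yaml(residue_table, histidine_charge=histidine_charge)
    functionals, model_name = load_functionals(functional_table)
    solvent, electrolyte = load_solvent(solvent_config)
    return ForceField(
        residues, functionals, solvent, electrolyte, model_name=model_name
    )
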