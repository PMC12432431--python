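"""Pair potentials: Wang-Frenkel (attractive and purely repulsive branches)
and the screened-Coulomb (Yukawa) electrostatic term.

The canonical Wang-Frenkel potential

    phi(r) = eps * alpha * [(sigma/r)^(2 mu) - 1] * [(R/r)^(2 mu) - 1]^(2 nu)

vanishes identically beyond its cutoff R = 3 sigma and, for eps > 0, has a
minimum of exactly -eps at the interior stationary point r*.  When a
temperature-scaled well depth becomes negative the canonical form would be
attractive at contact, which is unphysical; the revised branch

    phi_rep(r) = -phi_WF(r) - eps   for r <  r*
    phi_rep(r) = 0                  for r >= r*

is continuous at r*, everywhere non-negative, diverges at r -> 0, and
keeps the bead diameter of the canonical form.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .constants import COULOMB_PREFACTOR_KCAL_NM

__all__ = [
    "PairPotentialSpec",
    "wf_alpha",
    "find_rstar",
    "wf_potential",
    "wf_force",
    "repulsive_wf",
    "repulsive_wf_force",
    "yukawa",
    "yukawa_force",
    "pair_table",
]


def wf_alpha(sigma: float, R: float, mu: float, nu: float) -> float:
    """Normalizer making the canonical well depth equal eps.

    alpha = 2 nu (R/sigma)^(2 mu) *
            [ (2 nu + 1) / (2 nu ((R/sigma)^(2 mu) - 1)) ]^(2 nu + 1)

    Depends only on the ratio R/sigma.
    """
    if R <= sigma:
        raise ValueError(f"cutoff R={R} must exceed sigma={sigma}")
    x = (R / sigma) ** (2.0 * mu)
    return 2.0 * nu * x * ((2.0 * nu + 1.0) / (2.0 * nu * (x - 1.0))) ** (2.0 * nu + 1.0)


@dataclasses.dataclass(frozen=True)
class PairPotentialSpec:
    """Fully resolved pair interaction at one temperature.

    ``eps`` is signed: eps >= 0 selects the canonical attractive branch,
    eps < 0 the purely repulsive branch truncated at r*.
    """

    eps: float  # kcal/mol, signed
    sigma: float  # nm
    mu: float = 1.0
    nu: float = 1.0
    cutoff_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.cutoff_ratio <= 1:
            raise ValueError("cutoff must exceed sigma")

    @property
    def R(self) -> float:
        """Cutoff distance where the canonical potential vanishes (nm)."""
        return self.cutoff_ratio * self.sigma

    @property
    def alpha_wf(self) -> float:
        return wf_alpha(self.sigma, self.R, self.mu, self.nu)

    @property
    def r_star(self) -> float:
        return find_rstar(self)

    @property
    def repulsive(self) -> bool:
        return self.eps < 0


def find_rstar(spec: PairPotentialSpec) -> float:
    """Interior stationary point of the canonical Wang-Frenkel potential.

    Closed form r* = R [ (1 + 2 nu) / (1 + 2 nu (R/sigma)^(2 mu)) ]^(1/(2 mu));
    always satisfies sigma < r* < R.
    """
    x = (spec.R / spec.sigma) ** (2.0 * spec.mu)
    rstar = spec.R * ((1.0 + 2.0 * spec.nu) / (1.0 + 2.0 * spec.nu * x)) ** (
        1.0 / (2.0 * spec.mu)
    )
    if not (spec.sigma < rstar < spec.R):  # pragma: no cover - closed form guarantee
        raise RuntimeError("stationary point outside (sigma, R)")
    return rstar


def find_rstar_numeric(spec: PairPotentialSpec) -> float:
    """Bracketed root of d(phi_WF)/dr on (sigma, R); cross-check for find_rstar."""
    unit = dataclasses.replace(spec, eps=1.0)

    def dphi(r: float) -> float:
        return float(_wf_raw_deriv(np.asarray([r]), unit)[0])

    lo = spec.sigma * (1.0 + 1e-9)
    hi = spec.R * (1.0 - 1e-9)
    if dphi(lo) * dphi(hi) > 0:
        raise ValueError("failed to bracket a stationary point in (sigma, R)")
    return float(brentq(dphi, lo, hi, xtol=1e-14, rtol=1e-14))


def _wf_raw(r: np.ndarray, spec: PairPotentialSpec) -> np.ndarray:
    """Canonical form evaluated for r < R (no cutoff masking)."""
    a = spec.alpha_wf
    f = (spec.sigma / r) ** (2.0 * spec.mu) - 1.0
    g = (spec.R / r) ** (2.0 * spec.mu) - 1.0
    return spec.eps * a * f * g ** (2.0 * spec.nu)


def _wf_raw_deriv(r: np.ndarray, spec: PairPotentialSpec) -> np.ndarray:
    a = spec.alpha_wf
    two_mu = 2.0 * spec.mu
    f = (spec.sigma / r) ** two_mu - 1.0
    g = (spec.R / r) ** two_mu - 1.0
    fp = -two_mu * spec.sigma**two_mu * r ** (-two_mu - 1.0)
    gp = -two_mu * spec.R**two_mu * r ** (-two_mu - 1.0)
    return spec.eps * a * (
        fp * g ** (2.0 * spec.nu)
        + 2.0 * spec.nu * f * g ** (2.0 * spec.nu - 1.0) * gp
    )


def _check_r(r: np.ndarray) -> None:
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")


def wf_potential(r, spec: PairPotentialSpec):
    """Canonical Wang-Frenkel energy (kcal/mol); zero at and beyond R."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    _check_r(r)
    out = np.zeros_like(r)
    inside = r < spec.R
    if np.any(inside):
        out[inside] = _wf_raw(r[inside], spec)
    return out if out.size > 1 else float(out[0])


def wf_force(r, spec: PairPotentialSpec):
    """Radial force -d(phi)/dr of the canonical branch."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    _check_r(r)
    out = np.zeros_like(r)
    inside = r < spec.R
    if np.any(inside):
        out[inside] = -_wf_raw_deriv(r[inside], spec)
    return out if out.size > 1 else float(out[0])


def repulsive_wf(r, spec: PairPotentialSpec):
    """Purely repulsive branch for eps < 0: -phi_WF(r) - eps below r*, else 0."""
    if spec.eps >= 0:
        raise ValueError("repulsive branch requires eps < 0")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    _check_r(r)
    out = np.zeros_like(r)
    rstar = spec.r_star
    inside = r < rstar
    if np.any(inside):
        out[inside] = -_wf_raw(r[inside], spec) - spec.eps
    return out if out.size > 1 else float(out[0])


def repulsive_wf_force(r, spec: PairPotentialSpec):
    if spec.eps >= 0:
        raise ValueError("repulsive branch requires eps < 0")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    _check_r(r)
    out = np.zeros_like(r)
    inside = r < spec.r_star
    if np.any(inside):
        out[inside] = _wf_raw_deriv(r[inside], spec)
    return out if out.size > 1 else float(out[0])


def pair_potential(r, spec: PairPotentialSpec):
    """Energy on the branch selected by the sign of eps."""
    return repulsive_wf(r, spec) if spec.repulsive else wf_potential(r, spec)


def pair_force(r, spec: PairPotentialSpec):
    """Force on the branch selected by the sign of eps."""
    return repulsive_wf_force(r, spec) if spec.repulsive else wf_force(r, spec)


def yukawa(r, qi: float, qj: float, kappa: float, eps: float, cutoff: float | None = None):
    """Screened Coulomb energy (kcal/mol); plain truncation at ``cutoff`` nm."""
    if eps <= 0:
        raise ValueError("dielectric constant must be positive")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    _check_r(r)
    out = (
        COULOMB_PREFACTOR_KCAL_NM * qi * qj / eps * np.exp(-kappa * r) / r
    )
    if cutoff is not None:
        out = np.where(r < cutoff, out, 0.0)
    return out if out.size > 1 else float(out[0])


def yukawa_force(r, qi: float, qj: float, kappa: float, eps: float, cutoff: float | None = None):
    """Radial force of the truncated Yukawa term."""
    if eps <= 0:
        raise ValueError("dielectric constant must be positive")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    _check_r(r)
    pref = COULOMB_PREFACTOR_KCAL_NM * qi * qj / eps
    out = pref * np.exp(-kappa * r) * (kappa * r + 1.0) / r**2
    if cutoff is not None:
        out = np.where(r < cutoff, out, 0.0)
    return out if out.size > 1 else float(out[0])


def pair_table(spec: PairPotentialSpec, r_grid) -> tuple[np.ndarray, np.ndarray]:
    """Sample (energy, force) on a strictly increasing positive grid.

    The branch is selected by the sign of eps; forces are the analytic
    radial derivatives of the corresponding energies.
    """
    r = np.asarray(r_grid, dtype=float)
    if r.size == 0:
        raise ValueError("empty distance grid")
    if np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ValueError("distance grid must be positive and strictly increasing")
    return np.atleast_1d(pair_potential(r, spec)), np.atleast_1d(pair_force(r, spec))
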