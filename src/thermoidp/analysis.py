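"""Thermodynamic analysis of temperature scans.

Implements the bespoke analyses of the modelling workflow:

* finite-size cloud-point detection from slab z-density profiles (the
  first temperature whose profile develops a sharp condensate spike);
* the approximate Flory exponent nu from the radius of gyration of a
  finite heteropolymer, its inversion, and the theta temperature where
  nu crosses 0.5 (coil-to-globule transition; the LCST/UCST character
  follows from the sign of d(nu)/dT);
* dilute/dense coexistence densities from two-plateau slab profiles and
  critical-point estimation via the law of coexistence densities plus the
  law of rectilinear diameters;
* block averaging (three blocks by convention) and the absorbance-based
  experimental cloud point (absorbance 0.301 = transmittance one half).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "DensityProfile",
    "NuSeries",
    "BinodalDataset",
    "FloryConstants",
    "AnalysisError",
    "rg_from_nu",
    "nu_from_rg",
    "theta_temperature",
    "classify_transition",
    "cloud_fit",
    "coexistence_densities",
    "fit_binodal",
    "block_stats",
    "cloud_point_from_absorbance",
    "model_rmsd",
    "ABSORBANCE_THRESHOLD",
]

#: Absorbance at which transmittance has fallen to one half: -log10(0.5).
ABSORBANCE_THRESHOLD = float(-np.log10(0.5))


class AnalysisError(ValueError):
    pass


@dataclasses.dataclass
class DensityProfile:
    """z-binned mass-density profile of a slab system at one temperature.

    ``densities`` has shape (n_frames, n_bins); g/cm^3 per bin.
    """

    temperature: float  # K
    bin_centers: np.ndarray  # nm
    densities: np.ndarray  # (n_frames, n_bins) g/cm^3
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.densities = np.atleast_2d(np.asarray(self.densities, dtype=float))
        if self.densities.shape[1] != len(self.bin_centers):
            raise AnalysisError("density array does not match bin centers")
        if np.any(self.densities < 0):
            raise AnalysisError("negative bin density")
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0], rtol=1e-6):
            raise AnalysisError("bins must be uniform")

    @property
    def mean_profile(self) -> np.ndarray:
        return self.densities.mean(axis=0)


@dataclasses.dataclass
class NuSeries:
    """Flory exponent versus temperature (ascending)."""

    temperatures: np.ndarray
    nu_values: np.ndarray
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.nu_values = np.asarray(self.nu_values, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise AnalysisError("temperatures must be strictly increasing")
        if np.any((self.nu_values <= 0) | (self.nu_values >= 1)):
            raise AnalysisError("nu values must lie in (0, 1)")


@dataclasses.dataclass
class BinodalDataset:
    """Per-temperature coexistence densities plus fitted critical point."""

    temperatures: np.ndarray  # K
    rho_dilute: np.ndarray  # g/cm^3
    rho_dense: np.ndarray  # g/cm^3
    mode: str = "LCST"  # or "UCST"
    errors: np.ndarray | None = None
    tc: float | None = None
    rho_c: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rho_dilute = np.asarray(self.rho_dilute, dtype=float)
        self.rho_dense = np.asarray(self.rho_dense, dtype=float)
        if self.mode not in ("LCST", "UCST"):
            raise AnalysisError("mode must be LCST or UCST")
        if np.any(self.rho_dense <= self.rho_dilute):
            raise AnalysisError("dense arm must exceed dilute arm at every point")


@dataclasses.dataclass(frozen=True)
class FloryConstants:
    """Constants of the finite-chain radius-of-gyration relation."""

    b: float = 0.55  # nm prefactor (sqrt of persistence length x Ca-Ca distance)
    gamma: float = 1.1615
    nu_threshold: float = 0.5


# ---------------------------------------------------------------------------
# Flory machinery
# ---------------------------------------------------------------------------

def rg_from_nu(nu, n_bonds: int, const: FloryConstants = FloryConstants()):
    """Radius of gyration (nm) of a finite chain with Flory exponent nu.

    S = sqrt( g (g+1) / (2 (g+2 nu)(g+2 nu+1)) ) * b * N^nu with g = gamma
    and N the number of bonds.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any((nu <= 0) | (nu >= 1)):
        raise AnalysisError("nu must lie in (0, 1)")
    if n_bonds < 1:
        raise AnalysisError("N must be >= 1")
    g = const.gamma
    pref = np.sqrt(g * (g + 1.0) / (2.0 * (g + 2.0 * nu) * (g + 2.0 * nu + 1.0)))
    out = pref * const.b * float(n_bonds) ** nu
    return out if out.ndim else float(out)


def nu_from_rg(
    rg: float,
    n_bonds: int,
    const: FloryConstants = FloryConstants(),
    bracket: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Invert rg_from_nu by bracketed root finding (monotone in nu for N >= 2)."""
    lo, hi = bracket
    s_lo = rg_from_nu(lo, n_bonds, const)
    s_hi = rg_from_nu(hi, n_bonds, const)
    s_min, s_max = min(s_lo, s_hi), max(s_lo, s_hi)
    if not (s_min <= rg <= s_max):
        raise AnalysisError(
            f"Rg={rg:.4g} nm outside attainable range "
            f"[{s_min:.4g}, {s_max:.4g}] nm for nu in {bracket}, N={n_bonds}"
        )
    return float(
        brentq(lambda nu: rg_from_nu(nu, n_bonds, const) - rg, lo, hi, xtol=1e-12)
    )


def theta_temperature(
    series: NuSeries, const: FloryConstants = FloryConstants()
) -> float | None:
    """Temperature where nu crosses 0.5, by linear interpolation.

    Returns None when nu never crosses the threshold.  When several
    crossings exist, the lowest-temperature one is returned and a warning
    flags the multiplicity.
    """
    t = series.temperatures
    d = series.nu_values - const.nu_threshold
    if len(t) < 2:
        raise AnalysisError("need at least two temperatures")
    crossings = []
    for k in range(len(t) - 1):
        if d[k] == 0.0:
            crossings.append(float(t[k]))
        elif d[k] * d[k + 1] < 0:
            frac = d[k] / (d[k] - d[k + 1])
            crossings.append(float(t[k] + frac * (t[k + 1] - t[k])))
    if d[-1] == 0.0:
        crossings.append(float(t[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"nu crosses {const.nu_threshold} at {len(crossings)} temperatures; "
            "returning the lowest",
            stacklevel=2,
        )
    return min(crossings)


def classify_transition(series: NuSeries) -> str:
    """LCST-like when nu decreases with T (chains compact on heating), else UCST-like."""
    slope = np.polyfit(series.temperatures, series.nu_values, 1)[0]
    return "LCST" if slope < 0 else "UCST"


# ---------------------------------------------------------------------------
# cloud-point detection from density profiles
# ---------------------------------------------------------------------------

def _profile_has_spike(
    profile: DensityProfile, spike_factor: float, persistence: int
) -> bool:
    spiky = []
    for frame in profile.densities:
        med = float(np.median(frame))
        spiky.append(med > 0 and float(frame.max()) >= spike_factor * med)
    if len(spiky) < persistence:
        return all(spiky) and len(spiky) > 0
    run = 0
    for s in spiky:
        run = run + 1 if s else 0
        if run >= persistence:
            return True
    return False


def cloud_fit(
    profiles: list[DensityProfile],
    spike_factor: float = 3.0,
    persistence: int = 2,
) -> float | None:
    """Cloud point: lowest temperature whose z-density profile spikes.

    The detector flags a frame when its maximum bin density reaches
    ``spike_factor`` times the median bin density, and a temperature when
    at least ``persistence`` consecutive stored frames are flagged.
    Returns None when no scanned temperature qualifies.
    """
    if not profiles:
        raise AnalysisError("no profiles supplied")
    temps = [p.temperature for p in profiles]
    if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
        raise AnalysisError("profiles must be sorted by strictly increasing T")
    nbins = {p.densities.shape[1] for p in profiles}
    if len(nbins) != 1:
        raise AnalysisError("profiles must share binning")
    for idx, prof in enumerate(profiles):
        if _profile_has_spike(prof, spike_factor, persistence):
            if idx == 0:
                warnings.warn(
                    "spike already present at the lowest scanned temperature; "
                    "the true cloud point may lie below the scan range",
                    stacklevel=2,
                )
            return float(prof.temperature)
    return None


# ---------------------------------------------------------------------------
# coexistence densities and the critical point
# ---------------------------------------------------------------------------

def coexistence_densities(
    profile: DensityProfile,
    margin: float = 0.10,
    min_contrast: float = 0.2,
) -> tuple[float, float]:
    """(rho_dilute, rho_dense) from a two-plateau slab profile.

    The time-averaged profile is rolled so the dense slab is centered,
    split at the midpoint density, and each region is averaged over its
    interior after discarding ``margin`` of its width on each side
    (interfacial exclusion).
    """
    rho = profile.mean_profile
    lo, hi = float(rho.min()), float(rho.max())
    if hi <= 0 or (hi - lo) / hi < min_contrast:
        raise AnalysisError("no two-plateau structure: profile is single-phase")
    # center the dense region (periodic in z)
    n = len(rho)
    shift = n // 2 - int(np.argmax(rho))
    rho = np.roll(rho, shift)
    dense_mask = rho > 0.5 * (lo + hi)
    if dense_mask.all() or not dense_mask.any():
        raise AnalysisError("no two-plateau structure: profile is single-phase")
    dense_idx = np.nonzero(dense_mask)[0]
    # contiguous dense block around the center after rolling
    start, stop = dense_idx[0], dense_idx[-1] + 1
    width = stop - start
    trim = max(1, int(round(margin * width)))
    dense_core = rho[start + trim : stop - trim]
    if dense_core.size == 0:
        dense_core = rho[start:stop]
    dil = np.concatenate([rho[:start], rho[stop:]])
    dwidth = len(dil)
    dtrim = max(1, int(round(margin * dwidth)))
    # dilute region interior: drop bins adjacent to the two interfaces
    dil_core = np.concatenate([rho[stop + dtrim : n], rho[0 : start - dtrim]]) \
        if (start - dtrim > 0 or stop + dtrim < n) else dil
    if dil_core.size == 0:
        dil_core = dil
    rho_dense = float(dense_core.mean())
    rho_dilute = float(dil_core.mean())
    if rho_dense <= rho_dilute:
        raise AnalysisError("dense plateau does not exceed dilute plateau")
    return rho_dilute, rho_dense


def fit_binodal(
    data: BinodalDataset,
    beta: float = 0.325,
) -> tuple[float, float, dict]:
    """Critical point (Tc, rho_c) from coexistence data.

    Simultaneous unweighted least squares of the law of coexistence
    densities, rho_dense - rho_dilute = A |T - Tc|^beta, and the law of
    rectilinear diameters, (rho_dense + rho_dilute)/2 = rho_c + s |T - Tc|.
    For LCST data all temperatures satisfy T > Tc; for UCST, T < Tc.
    """
    t = data.temperatures
    if len(t) < 3:
        raise AnalysisError("need at least 3 coexistence points")
    delta = data.rho_dense - data.rho_dilute
    mid = 0.5 * (data.rho_dense + data.rho_dilute)
    sign = 1.0 if data.mode == "LCST" else -1.0
    t_edge = t.min() if data.mode == "LCST" else t.max()

    span = max(t.max() - t.min(), 1.0)

    def unpack(p):
        # Tc parameterized as an offset from the data edge on the correct side
        tc = t_edge - sign * np.exp(p[0])
        return tc, p[1], p[2], p[3]  # tc, log A handled linearly below

    def residuals(p):
        tc, a, rc, s = unpack(p)
        dt = np.abs(t - tc)
        return np.concatenate([a * dt**beta - delta, rc + s * dt - mid])

    # initial guesses: Tc just outside the data, amplitudes by crude regression
    dt0 = np.abs(t - (t_edge - sign * 0.5 * span))
    a0 = float(np.mean(delta / dt0**beta))
    s0 = float(np.polyfit(dt0, mid, 1)[0])
    rc0 = float(np.polyfit(dt0, mid, 1)[1])
    p0 = np.array([np.log(0.5 * span), a0, rc0, s0])
    sol = least_squares(residuals, p0, method="lm", xtol=1e-15, ftol=1e-15)
    if not sol.success:
        raise AnalysisError(f"binodal fit failed to converge: {sol.message}")
    tc, a, rho_c, s = unpack(sol.x)
    diag = {
        "amplitude": float(a),
        "diameter_slope": float(s),
        "beta": beta,
        "cost": float(sol.cost),
        "rms_residual": float(np.sqrt(np.mean(sol.fun**2))),
    }
    data.tc = float(tc)
    data.rho_c = float(rho_c)
    return float(tc), float(rho_c), diag


# ---------------------------------------------------------------------------
# block statistics, absorbance cloud points, model comparison
# ---------------------------------------------------------------------------

def block_stats(series, n_blocks: int = 3) -> tuple[float, float]:
    """Mean of contiguous block means and their standard error.

    The series is split into ``n_blocks`` contiguous equal blocks (any
    remainder joins the last block); SE = sd(block means)/sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < n_blocks:
        raise AnalysisError(f"series of length {len(x)} shorter than {n_blocks} blocks")
    size = len(x) // n_blocks
    means = [
        x[k * size : (k + 1) * size if k < n_blocks - 1 else len(x)].mean()
        for k in range(n_blocks)
    ]
    means = np.asarray(means)
    se = float(means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return float(means.mean()), se


def cloud_point_from_absorbance(curve) -> float:
    """Cloud point from a (T, absorbance) turbidity curve.

    Linear interpolation of the first upward crossing of absorbance
    0.30103 (= -log10(0.5), transmittance one half).
    """
    pts = sorted((float(t), float(a)) for t, a in curve)
    temps = np.array([p[0] for p in pts])
    absb = np.array([p[1] for p in pts])
    thr = ABSORBANCE_THRESHOLD
    if absb[0] >= thr:
        warnings.warn(
            "absorbance already above threshold at the first point; "
            "returning the boundary temperature",
            stacklevel=2,
        )
        return float(temps[0])
    for k in range(len(temps) - 1):
        if absb[k] < thr <= absb[k + 1]:
            frac = (thr - absb[k]) / (absb[k + 1] - absb[k])
            return float(temps[k] + frac * (temps[k + 1] - temps[k]))
    raise AnalysisError("absorbance never crosses the 0.301 threshold")


def model_rmsd(simulated, experimental) -> float:
    """Root-mean-square deviation between paired cloud-point lists (K)."""
    sim = np.asarray(simulated, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if sim.shape != exp.shape or sim.size == 0:
        raise AnalysisError("lists must be non-empty and of equal length")
    return float(np.sqrt(np.mean((sim - exp) ** 2)))
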