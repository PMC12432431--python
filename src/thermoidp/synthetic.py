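"""Deterministic synthetic-data generators.

Closed-loop test doubles for the analysis stack: ELP-like repeat
sequences, slab z-density profiles with and without condensate spikes,
binodal coexistence points generated exactly from the scaling laws, and
Rg(T) curves built from a prescribed Flory-exponent trajectory.  Every
generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .analysis import BinodalDataset, DensityProfile, FloryConstants, rg_from_nu
from .sequences import CANONICAL_RESIDUES, SequenceError

DEFAULT_MOTIF = "VPGXG"


def elp_sequence(guest: str, n_repeats: int, motif: str = DEFAULT_MOTIF) -> str:
    """Concatenated xPxxG-type repeats with guest residue at the X slots.

    The default motif realization is VPGXG, the most common
    elastin-like-polypeptide repeat.
    """
    if guest not in CANONICAL_RESIDUES:
        raise SequenceError(f"invalid guest residue {guest!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return motif.replace("X", guest) * n_repeats


def synthetic_profiles(
    t_grid,
    spike_onset_T: float,
    spike_factor: float = 5.0,
    noise_sd: float = 0.002,
    seed: int = 0,
    n_bins: int = 100,
    n_frames: int = 5,
    baseline: float = 0.05,
    box_length_nm: float = 100.0,
) -> list[DensityProfile]:
    """Flat noisy profiles below onset; Gaussian condensate spike above.

    At and above ``spike_onset_T`` the peak bin density reaches
    ``spike_factor`` times the baseline in every stored frame.
    """
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_bins) + 0.5) * box_length_nm / n_bins
    profiles = []
    mid = box_length_nm / 2.0
    width = box_length_nm / 30.0
    for T in np.asarray(t_grid, dtype=float):
        dens = baseline + noise_sd * rng.standard_normal((n_frames, n_bins))
        if T >= spike_onset_T and spike_factor > 1.0:
            spike = (spike_factor - 1.0) * baseline * np.exp(
                -0.5 * ((centers - mid) / width) ** 2
            )
            dens = dens + spike[None, :]
        profiles.append(
            DensityProfile(
                temperature=float(T),
                bin_centers=centers,
                densities=np.clip(dens, 0.0, None),
                frame_times=np.arange(n_frames, dtype=float),
            )
        )
    return profiles


def synthetic_binodal(
    tc: float = 300.0,
    rho_c: float = 0.3,
    amplitude: float = 0.12,
    slope: float = 0.004,
    beta: float = 0.325,
    t_offsets=(5.0, 10.0, 20.0, 30.0, 45.0, 60.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    mode: str = "LCST",
) -> BinodalDataset:
    """Coexistence points generated exactly from the two critical laws.

    rho_dense - rho_dilute = amplitude * |T - Tc|^beta and
    (rho_dense + rho_dilute)/2 = rho_c + slope * |T - Tc|, plus optional
    seeded multiplicative Gaussian noise on both arms.
    """
    if amplitude <= 0:
        raise ValueError("zero or negative amplitude gives coincident arms")
    offs = np.asarray(t_offsets, dtype=float)
    if np.any(offs <= 0):
        raise ValueError("temperature offsets must be positive")
    sign = 1.0 if mode == "LCST" else -1.0
    temps = tc + sign * offs
    delta = amplitude * offs**beta
    mid = rho_c + slope * offs
    dil = mid - 0.5 * delta
    den = mid + 0.5 * delta
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dil = dil * (1.0 + noise_sd * rng.standard_normal(len(offs)))
        den = den * (1.0 + noise_sd * rng.standard_normal(len(offs)))
    if np.any(dil < 0):
        raise ValueError("parameters yield negative dilute-arm densities")
    order = np.argsort(temps)
    return BinodalDataset(
        temperatures=temps[order],
        rho_dilute=dil[order],
        rho_dense=den[order],
        mode=mode,
    )


def synthetic_rg_curve(
    n_bonds: int = 150,
    nu_start: float = 0.6,
    nu_end: float = 0.4,
    t_grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    const: FloryConstants = FloryConstants(),
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Rg(T) built from a linear nu(T) ramp.

    Returns (temperatures, rg_nm, theta_true) where theta_true is the
    temperature at which the constructed nu(T) crosses 0.5 (None if it
    never does).
    """
    if t_grid is None:
        t_grid = np.arange(280.0, 371.0, 10.0)
    t = np.asarray(t_grid, dtype=float)
    nu = nu_start + (nu_end - nu_start) * (t - t[0]) / (t[-1] - t[0])
    if np.any((nu <= 0.05) | (nu >= 0.95)):
        raise ValueError("nu ramp leaves the invertible range (0.05, 0.95)")
    rg = np.array([rg_from_nu(v, n_bonds, const) for v in nu])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rg = rg * (1.0 + noise_sd * rng.standard_normal(len(t)))
    theta = None
    d = nu - const.nu_threshold
    for k in range(len(t) - 1):
        if d[k] == 0.0:
            theta = float(t[k]); break
        if d[k] * d[k + 1] < 0:
            theta = float(t[k] + d[k] / (d[k] - d[k + 1]) * (t[k + 1] - t[k]))
            break
    return t, rg, theta
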