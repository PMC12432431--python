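"""Desk-scale Langevin-dynamics engine.

A minimal NVT sampler for bead-spring chains under harmonic bonds,
Wang-Frenkel nonbonded interactions (attractive and purely repulsive
branches) and truncated Yukawa electrostatics, with minimum-image periodic
boundaries and a Verlet neighbor list.  Integration uses the BAOAB
splitting of Langevin dynamics, which reduces to velocity Verlet when the
friction is switched off.

Intended for single-chain and small multi-chain systems (validation,
desk-scale exploration); production slab runs are expected to go through
the exported MD-engine inputs (see :mod:`thermoidp.lammps`).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import AVOGADRO, KB_KCAL, KCAL_TO_INTERNAL
from .forcefield import ForceField
from .sequences import ChainTopology, build_chain

#: amu/nm^3 per g/cm^3
DENSITY_AMU_NM3 = AVOGADRO / 1e21 / 1e3 * 1.0e3  # = 602.214076


class EngineError(RuntimeError):
    pass


@dataclasses.dataclass
class SimSystem:
    """Coordinates, topology and interaction parameters resolved at one T."""

    coords: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm, orthorhombic, periodic
    chains: list[ChainTopology]
    chain_slices: list[tuple[int, int]]
    masses: np.ndarray  # (N,) amu
    charges: np.ndarray  # (N,) e
    type_of: np.ndarray  # (N,) int index into type_codes
    type_codes: list[str]
    pair_eps: np.ndarray  # (nt, nt) kcal/mol, signed
    pair_sigma: np.ndarray  # (nt, nt) nm
    pair_R: np.ndarray  # (nt, nt) nm cutoff of canonical branch
    pair_alpha: np.ndarray  # (nt, nt)
    pair_rstar: np.ndarray  # (nt, nt) nm
    wf_mu: float
    wf_nu: float
    kappa: float  # nm^-1
    eps_r: float
    yukawa_cutoff: float  # nm
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_k: np.ndarray  # kcal/mol/nm^2, U = 0.5 k dr^2
    bond_r0: np.ndarray
    temperature: float
    include_nonbonded: bool = True

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def max_cutoff(self) -> float:
        cut = float(self.pair_R.max()) if self.pair_R.size else 0.0
        if np.any(self.charges != 0):
            cut = max(cut, self.yukawa_cutoff)
        return cut

    def wrapped_coords(self) -> np.ndarray:
        return np.mod(self.coords, self.box)


@dataclasses.dataclass
class Trajectory:
    """Sampled frames plus per-frame thermodynamic observables."""

    times: np.ndarray  # ps, strictly increasing
    frames: np.ndarray  # (n_frames, N, 3) nm, unwrapped
    potential: np.ndarray  # kcal/mol
    kinetic: np.ndarray  # kcal/mol
    temperature: np.ndarray  # K instantaneous

    @property
    def n_frames(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def _chains_to_system(
    chains: list[ChainTopology],
    coords: np.ndarray,
    box: np.ndarray,
    forcefield: ForceField,
    temperature: float,
    include_nonbonded: bool = True,
) -> SimSystem:
    from .potentials import PairPotentialSpec, find_rstar, wf_alpha

    type_codes = sorted({c for ch in chains for c in ch.sequence})
    t_index = {c: k for k, c in enumerate(type_codes)}
    nt = len(type_codes)

    masses, charges, type_of = [], [], []
    bond_i, bond_j, bond_k, bond_r0 = [], [], [], []
    slices = []
    offset = 0
    for ch in chains:
        slices.append((offset, offset + ch.n_beads))
        for bead in ch.beads:
            masses.append(bead.mass)
            charges.append(bead.charge)
            type_of.append(t_index[bead.code])
        for b in ch.bonds:
            bond_i.append(offset + b.i)
            bond_j.append(offset + b.j)
            bond_k.append(b.k)
            bond_r0.append(b.r0)
        offset += ch.n_beads

    pair_eps = np.zeros((nt, nt))
    pair_sigma = np.zeros((nt, nt))
    pair_R = np.zeros((nt, nt))
    pair_alpha = np.zeros((nt, nt))
    pair_rstar = np.zeros((nt, nt))
    for a, ca in enumerate(type_codes):
        for b, cb in enumerate(type_codes):
            eps = forcefield.epsilon_ij(temperature, ca, cb)
            sig = forcefield.sigma_ij(ca, cb)
            spec = PairPotentialSpec(
                eps=eps, sigma=sig,
                mu=forcefield.residues.wf_mu, nu=forcefield.residues.wf_nu,
            )
            pair_eps[a, b] = eps
            pair_sigma[a, b] = sig
            pair_R[a, b] = spec.R
            pair_alpha[a, b] = wf_alpha(sig, spec.R, spec.mu, spec.nu)
            pair_rstar[a, b] = find_rstar(spec)

    box = np.asarray(box, dtype=float)
    # plain truncation cannot exceed the minimum-image radius
    yuk_cut = min(forcefield.residues.yukawa_cutoff, float(box.min()) / 2.001)

    return SimSystem(
        coords=np.asarray(coords, dtype=float).copy(),
        box=box,
        chains=chains,
        chain_slices=slices,
        masses=np.asarray(masses, dtype=float),
        charges=np.asarray(charges, dtype=float),
        type_of=np.asarray(type_of, dtype=np.intp),
        type_codes=type_codes,
        pair_eps=pair_eps,
        pair_sigma=pair_sigma,
        pair_R=pair_R,
        pair_alpha=pair_alpha,
        pair_rstar=pair_rstar,
        wf_mu=forcefield.residues.wf_mu,
        wf_nu=forcefield.residues.wf_nu,
        kappa=forcefield.kappa(temperature),
        eps_r=forcefield.dielectric(temperature),
        yukawa_cutoff=yuk_cut,
        bond_i=np.asarray(bond_i, dtype=np.intp),
        bond_j=np.asarray(bond_j, dtype=np.intp),
        bond_k=np.asarray(bond_k, dtype=float),
        bond_r0=np.asarray(bond_r0, dtype=float),
        temperature=float(temperature),
        include_nonbonded=include_nonbonded,
    )


def _self_avoiding_walk(
    n: int, r0: float, min_sep: float, rng: np.random.Generator,
    origin: np.ndarray, confine_radius: float | None = None,
    max_trials: int = 200, restarts: int = 20,
) -> np.ndarray:
    coords = np.empty((n, 3))
    for attempt in range(restarts):
        coords[0] = origin
        stalled = False
        for i in range(1, n):
            for _ in range(max_trials):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = coords[i - 1] + r0 * v
                if confine_radius is not None and np.linalg.norm(cand - origin) > confine_radius:
                    continue
                if i > 1:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                coords[i] = cand
                break
            else:
                stalled = True
                break
        if not stalled:
            return coords
    raise EngineError(f"self-avoiding walk stalled after {restarts} restarts")


def build_single_chain(
    sequence: str,
    forcefield: ForceField,
    temperature: float,
    box_size: float,
    seed: int = 0,
) -> SimSystem:
    """One chain, initialized as a seeded self-avoiding walk.

    The box must accommodate the fully extended chain; initial
    conformations have no pair closer than 0.7 sigma.
    """
    chain = build_chain(sequence, forcefield.residues)
    contour = chain.n_bonds * forcefield.residues.bond_r0
    if box_size < contour:
        raise EngineError(
            f"box ({box_size} nm) smaller than chain contour length ({contour:.2f} nm)"
        )
    rng = np.random.default_rng(seed)
    min_sigma = min(b.sigma for b in chain.beads)
    coords = _self_avoiding_walk(
        chain.n_beads, forcefield.residues.bond_r0, 0.7 * min_sigma, rng,
        origin=np.full(3, box_size / 2.0),
    )
    return _chains_to_system(
        [chain], coords, np.full(3, float(box_size)), forcefield, temperature
    )


def build_slab(
    sequence: str,
    forcefield: ForceField,
    temperature: float,
    target_concentration: float,
    dense_density: float = 0.9,
    seed: int = 0,
    relax_steps: int = 200,
) -> SimSystem:
    """Multi-chain slab at a target system concentration.

    64 (4x4x4) chain replicates for sequences shorter than 190 residues,
    27 (3x3x3) otherwise.  Chains are packed as compact coils in a central
    dense slab at ``dense_density`` (g/cm^3) and the z edge of the periodic
    box is extended so that total mass / box volume equals
    ``target_concentration`` (g/L).  Overlaps are relaxed by a short
    steepest-descent minimization.
    """
    if not (0.8 <= dense_density <= 1.0):
        raise EngineError("dense_density must lie in the 0.8-1.0 g/cm^3 window")
    chain = build_chain(sequence, forcefield.residues)
    grid = 4 if chain.n_beads < 190 else 3
    n_chains = grid**3

    m_chain = chain.total_mass  # amu
    rho_dense = dense_density * DENSITY_AMU_NM3  # amu/nm^3
    cell = (m_chain / rho_dense) ** (1.0 / 3.0)  # nm, cubic cell per chain
    lxy = grid * cell
    slab_h = grid * cell
    total_mass = n_chains * m_chain
    c_target = target_concentration * 1e-3 * DENSITY_AMU_NM3  # amu/nm^3
    lz = total_mass / (c_target * lxy * lxy)
    if lz < slab_h:
        raise EngineError(
            "target concentration exceeds the dense slab density"
        )

    rng = np.random.default_rng(seed)
    r0 = forcefield.residues.bond_r0
    min_sigma = min(b.sigma for b in chain.beads)
    coords = []
    z0 = (lz - slab_h) / 2.0
    for ix in range(grid):
        for iy in range(grid):
            for iz in range(grid):
                center = np.array(
                    [(ix + 0.5) * cell, (iy + 0.5) * cell, z0 + (iz + 0.5) * cell]
                )
                # looser contact criterion here: residual clashes are removed
                # by the steepest-descent relaxation below
                coords.append(
                    _self_avoiding_walk(
                        chain.n_beads, r0, 0.55 * min_sigma, rng,
                        origin=center, confine_radius=0.62 * cell,
                    )
                )
    coords = np.concatenate(coords, axis=0)
    system = _chains_to_system(
        [build_chain(sequence, forcefield.residues) for _ in range(n_chains)],
        coords,
        np.array([lxy, lxy, lz]),
        forcefield,
        temperature,
    )
    if relax_steps:
        minimize(system, max_steps=relax_steps)
    return system


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

class NeighborList:
    """Verlet pair list with skin; rebuilds when displacements demand it."""

    def __init__(self, system: SimSystem, skin: float = 0.3, chunk: int = 512) -> None:
        self.system = system
        self.skin = skin
        self.chunk = chunk
        self.pairs: tuple[np.ndarray, np.ndarray] | None = None
        self._ref_coords: np.ndarray | None = None
        n = system.n_beads
        lo = np.minimum(system.bond_i, system.bond_j)
        hi = np.maximum(system.bond_i, system.bond_j)
        self._excluded_keys = np.sort(lo.astype(np.int64) * n + hi)

    def _drop_excluded(
        self, i: np.ndarray, j: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        if not len(self._excluded_keys):
            return i, j
        keys = i.astype(np.int64) * self.system.n_beads + j
        mask = ~np.isin(keys, self._excluded_keys, assume_unique=False)
        return i[mask], j[mask]

    def build(self, coords: np.ndarray) -> None:
        sys = self.system
        cutoff = sys.max_cutoff + self.skin
        n = len(coords)
        box = sys.box
        ii, jj = [], []
        for start in range(0, n, self.chunk):
            stop = min(start + self.chunk, n)
            dx = coords[start:stop, None, :] - coords[None, :, :]
            dx -= box * np.round(dx / box)
            r2 = np.einsum("ijk,ijk->ij", dx, dx)
            a, b = np.nonzero(r2 < cutoff * cutoff)
            a = a + start
            keep = a < b
            ii.append(a[keep])
            jj.append(b[keep])
        i, j = self._drop_excluded(np.concatenate(ii), np.concatenate(jj))
        self._finalize(i, j, coords)

    def maybe_rebuild(self, coords: np.ndarray) -> None:
        if self.pairs is None or self._ref_coords is None:
            self.build(coords)
            return
        disp = np.abs(coords - self._ref_coords).max()
        if disp > self.skin / 2.0:
            self.build(coords)

    def all_pairs(self, coords: np.ndarray) -> None:
        """Exhaustive non-excluded pair list (oracle mode, no cutoff prefilter)."""
        n = len(coords)
        i, j = self._drop_excluded(*np.triu_indices(n, k=1))
        self._finalize(i, j, coords)
        self.skin = np.inf  # never auto-rebuild

    def _finalize(self, i: np.ndarray, j: np.ndarray, coords: np.ndarray) -> None:
        """Cache per-pair parameters; they change only with the pair list."""
        sys = self.system
        ti, tj = sys.type_of[i], sys.type_of[j]
        self.pair_params = {
            "eps": sys.pair_eps[ti, tj],
            "sig2": sys.pair_sigma[ti, tj] ** 2,
            "Rc": sys.pair_R[ti, tj],
            "Rc2": sys.pair_R[ti, tj] ** 2,
            "al": sys.pair_alpha[ti, tj],
            "rstar": sys.pair_rstar[ti, tj],
            "qq": sys.charges[i] * sys.charges[j],
        }
        self.pairs = (i, j)
        self._ref_coords = coords.copy()


def _ipow(base: np.ndarray, p: float) -> np.ndarray:
    if p == 1.0:
        return base
    if p == 2.0:
        return base * base
    if p == 3.0:
        return base * base * base
    return base**p


def _accumulate(forces: np.ndarray, i: np.ndarray, j: np.ndarray, fvec: np.ndarray) -> None:
    n = len(forces)
    for d in range(3):
        forces[:, d] += np.bincount(i, weights=fvec[:, d], minlength=n)
        forces[:, d] -= np.bincount(j, weights=fvec[:, d], minlength=n)


def compute_forces(
    system: SimSystem,
    coords: np.ndarray | None = None,
    nlist: NeighborList | None = None,
) -> tuple[float, np.ndarray]:
    """Potential energy (kcal/mol) and forces (kcal/mol/nm)."""
    if coords is None:
        coords = system.coords
    forces = np.zeros_like(coords)
    pe = 0.0
    box = system.box
    errstate = np.errstate(divide="ignore", invalid="ignore", over="ignore")
    errstate.__enter__()  # overlaps surface as a checked EngineError below

    # bonds
    if len(system.bond_i):
        dx = coords[system.bond_i] - coords[system.bond_j]
        dx -= box * np.round(dx / box)
        r = np.sqrt((dx**2).sum(axis=1))
        dr = r - system.bond_r0
        pe += float(0.5 * (system.bond_k * dr**2).sum())
        fmag = -system.bond_k * dr / r
        fvec = fmag[:, None] * dx
        _accumulate(forces, system.bond_i, system.bond_j, fvec)

    if system.include_nonbonded:
        if nlist is None:
            nlist = NeighborList(system)
            nlist.build(coords)
        i, j = nlist.pairs
        if len(i):
            dx = coords[i] - coords[j]
            dx -= box * np.round(dx / box)
            r2 = (dx**2).sum(axis=1)
            r = np.sqrt(r2)
            p = nlist.pair_params

            eps = p["eps"]
            al = p["al"]
            rep = eps < 0
            act = np.where(rep, r < p["rstar"], r < p["Rc"])
            if np.any(act):
                ra = r[act]
                ra2 = r2[act]
                mu_, nu_ = system.wf_mu, system.wf_nu
                two_mu = 2.0 * mu_
                # (x/r)^(2 mu) via squared ratios; fast paths for integer mu/nu
                xs = _ipow(p["sig2"][act] / ra2, mu_)
                xr = _ipow(p["Rc2"][act] / ra2, mu_)
                f1 = xs - 1.0
                g = xr - 1.0
                g2nu = _ipow(g, 2.0 * nu_)
                ea = eps[act] * al[act]
                raw = ea * f1 * g2nu
                fp = -two_mu * xs / ra
                gp = -two_mu * xr / ra
                draw = ea * (
                    fp * g2nu + 2.0 * nu_ * f1 * _ipow(g, 2.0 * nu_ - 1.0) * gp
                )
                repa = rep[act]
                energy = np.where(repa, -raw - eps[act], raw)
                fmag = np.where(repa, draw, -draw)  # -dU/dr
                pe += float(energy.sum())
                fvec = (fmag / ra)[:, None] * dx[act]
                _accumulate(forces, i[act], j[act], fvec)

            qq = p["qq"]
            ely = (qq != 0) & (r < system.yukawa_cutoff)
            if np.any(ely):
                from .constants import COULOMB_PREFACTOR_KCAL_NM

                re = r[ely]
                pref = COULOMB_PREFACTOR_KCAL_NM * qq[ely] / system.eps_r
                expf = np.exp(-system.kappa * re)
                pe += float((pref * expf / re).sum())
                fmag = pref * expf * (system.kappa * re + 1.0) / re**2
                fvec = (fmag / re)[:, None] * dx[ely]
                _accumulate(forces, i[ely], j[ely], fvec)

    errstate.__exit__(None, None, None)
    if not np.all(np.isfinite(forces)):
        bad = np.unique(np.nonzero(~np.isfinite(forces))[0])
        raise EngineError(
            f"non-finite force (overlap?) on beads {bad[:10].tolist()}"
        )
    return pe, forces


def minimize(
    system: SimSystem,
    max_steps: int = 200,
    max_disp: float = 0.02,
    fmax: float = 10.0,
) -> float:
    """Capped steepest descent; relaxes bad contacts in constructed systems."""
    nlist = NeighborList(system)
    coords = system.coords
    pe = np.inf
    for _ in range(max_steps):
        nlist.maybe_rebuild(coords)
        pe, forces = compute_forces(system, coords, nlist)
        fnorm = np.linalg.norm(forces, axis=1).max()
        if fnorm < fmax:
            break
        step = min(max_disp / fnorm, 1e-4)
        coords = coords + step * forces
    system.coords = coords
    return float(pe)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def run_langevin(
    system: SimSystem,
    temperature: float | None = None,
    n_steps: int = 1000,
    dt_fs: float = 10.0,
    damping_ps: float = 5.0,
    seed: int = 0,
    sample_every: int = 1000,
    thermostat: bool = True,
    use_neighbor_list: bool = True,
    initial_velocities: np.ndarray | None = None,
) -> Trajectory:
    """BAOAB Langevin dynamics; identical seed gives identical trajectories.

    ``thermostat=False`` (or ``damping_ps=inf``) degenerates to velocity
    Verlet for symplectic-drift checks.  Frames (including the initial
    one) are stored every ``sample_every`` steps.
    """
    if temperature is None:
        temperature = system.temperature
    dt = dt_fs * 1e-3  # ps
    kbt = KB_KCAL * temperature * KCAL_TO_INTERNAL  # amu nm^2/ps^2
    m = system.masses[:, None]
    rng = np.random.default_rng(seed)

    coords = system.coords.copy()
    if initial_velocities is not None:
        vel = np.asarray(initial_velocities, dtype=float).copy()
    else:
        vel = rng.normal(size=coords.shape) * np.sqrt(kbt / m)

    if thermostat and np.isfinite(damping_ps):
        gamma = 1.0 / damping_ps
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
    else:
        c1, c2 = 1.0, 0.0

    nlist = NeighborList(system) if system.include_nonbonded else None
    if nlist is not None:
        if use_neighbor_list:
            nlist.build(coords)
        else:
            nlist.all_pairs(coords)

    def observe(pe: float) -> tuple[float, float, float]:
        ke_int = 0.5 * float((system.masses * (vel**2).sum(axis=1)).sum())
        ke = ke_int / KCAL_TO_INTERNAL
        t_inst = 2.0 * ke / (3.0 * system.n_beads * KB_KCAL)
        return pe, ke, t_inst

    pe, forces = compute_forces(system, coords, nlist)
    times, frames, pes, kes, tis = [0.0], [coords.copy()], [], [], []
    p, k, t = observe(pe)
    pes.append(p); kes.append(k); tis.append(t)

    acc = forces * (KCAL_TO_INTERNAL / m)  # nm/ps^2
    sqrt_kbt_m = np.sqrt(kbt / m)
    for step in range(1, n_steps + 1):
        vel = vel + 0.5 * dt * acc
        coords = coords + 0.5 * dt * vel
        if c2 != 0.0:
            vel = c1 * vel + c2 * sqrt_kbt_m * rng.normal(size=vel.shape)
        coords = coords + 0.5 * dt * vel
        if nlist is not None and use_neighbor_list:
            nlist.maybe_rebuild(coords)
        pe, forces = compute_forces(system, coords, nlist)
        acc = forces * (KCAL_TO_INTERNAL / m)
        vel = vel + 0.5 * dt * acc
        if step % sample_every == 0 or step == n_steps:
            times.append(step * dt)
            frames.append(coords.copy())
            p, k, t = observe(pe)
            pes.append(p); kes.append(k); tis.append(t)

    system.coords = coords
    return Trajectory(
        times=np.asarray(times),
        frames=np.asarray(frames),
        potential=np.asarray(pes),
        kinetic=np.asarray(kes),
        temperature=np.asarray(tis),
    )


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def unwrap_chain(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Rebuild a connected chain across periodic images (minimum-image walk)."""
    out = np.empty_like(coords)
    out[0] = coords[0]
    deltas = coords[1:] - coords[:-1]
    deltas -= box * np.round(deltas / box)
    out[1:] = out[0] + np.cumsum(deltas, axis=0)
    return out


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    com = np.average(coords, axis=0, weights=masses)
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(d2, weights=masses)))


def rg_series(traj: Trajectory, system: SimSystem, chain_index: int = 0) -> np.ndarray:
    """Mass-weighted radius of gyration per stored frame (nm)."""
    if not (0 <= chain_index < len(system.chain_slices)):
        raise IndexError(f"chain index {chain_index} out of range")
    lo, hi = system.chain_slices[chain_index]
    masses = system.masses[lo:hi]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        chain_coords = unwrap_chain(traj.frames[f, lo:hi], system.box)
        out[f] = radius_of_gyration(chain_coords, masses)
    return out


def write_xyz(path, traj: Trajectory, system: SimSystem) -> None:
    """Plain-text XYZ trajectory export (element column = residue code)."""
    codes = [system.type_codes[t] for t in system.type_of]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{system.n_beads}\n")
            fh.write(f"t= {traj.times[f]:.4f} ps\n")
            for code, (x, y, z) in zip(codes, traj.frames[f]):
                fh.write(f"{code} {x*10:.6f} {y*10:.6f} {z*10:.6f}\n")


def write_thermo(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write("time_ps\tpotential_kcal_mol\tkinetic_kcal_mol\ttemperature_K\n")
        for row in zip(traj.times, traj.potential, traj.kinetic, traj.temperature):
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
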