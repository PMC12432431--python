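"""LAMMPS bridge: write production inputs, read back chunk profiles.

Exports use the ``real`` unit convention (kcal/mol, Angstrom, fs):

* a molecular data file (Masses / Atoms full / Bonds) matching the
  in-memory system;
* one tabulated pair-potential file with a keyed section per residue-type
  pair, resolved at the export temperature (energy kcal/mol, force
  kcal/mol/A);
* an input script encoding the slab protocol: Langevin thermostat with
  5 ps relaxation, 10 fs timestep, 50 ns equilibration + 400 ns
  production, z-density chunk profile every 1 ns.

Readers parse the data file and ``fix ave/chunk`` text profiles back into
package objects (bin centers in nm, mass density in g/cm^3 as produced by
``density/mass`` under real units).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .analysis import DensityProfile
from .constants import NM_TO_ANGSTROM
from .engine import SimSystem
from .forcefield import ForceField
from .potentials import pair_table as _pair_table
from .potentials import pair_potential


class LammpsFormatError(ValueError):
    pass


@dataclasses.dataclass
class Protocol:
    """Run-control settings for the exported slab protocol."""

    timestep_fs: float = 10.0
    damping_ps: float = 5.0
    equilibration_ns: float = 50.0
    production_ns: float = 400.0
    profile_every_ns: float = 1.0
    bin_width_nm: float = 1.0
    table_points: int = 5000
    table_inner_nm: float = 0.01

    @property
    def equilibration_steps(self) -> int:
        return int(round(self.equilibration_ns * 1e6 / self.timestep_fs))

    @property
    def production_steps(self) -> int:
        return int(round(self.production_ns * 1e6 / self.timestep_fs))


@dataclasses.dataclass
class EngineExport:
    data_file: Path
    table_file: Path
    input_script: Path
    pair_names: list[str]


def _pair_key(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"WF_{a}_{b}"


def write_data_file(path: str | Path, system: SimSystem) -> None:
    box = system.box * NM_TO_ANGSTROM
    coords = system.wrapped_coords() * NM_TO_ANGSTROM
    nt = len(system.type_codes)
    lines = ["# bead-spring protein data file (units real)", ""]
    lines.append(f"{system.n_beads} atoms")
    lines.append(f"{len(system.bond_i)} bonds")
    lines.append(f"{nt} atom types")
    lines.append("1 bond types")
    lines.append("")
    lines.append(f"0.0 {box[0]:.8f} xlo xhi")
    lines.append(f"0.0 {box[1]:.8f} ylo yhi")
    lines.append(f"0.0 {box[2]:.8f} zlo zhi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    type_mass = {}
    for t, m in zip(system.type_of, system.masses):
        type_mass[int(t)] = float(m)
    for t in range(nt):
        lines.append(f"{t + 1} {type_mass[t]:.6f}  # {system.type_codes[t]}")
    lines.append("")
    lines.append("Atoms  # full")
    lines.append("")
    mol_of = np.empty(system.n_beads, dtype=int)
    for mol, (lo, hi) in enumerate(system.chain_slices, start=1):
        mol_of[lo:hi] = mol
    for idx in range(system.n_beads):
        x, y, z = coords[idx]
        lines.append(
            f"{idx + 1} {mol_of[idx]} {int(system.type_of[idx]) + 1} "
            f"{system.charges[idx]:.6f} {x:.10f} {y:.10f} {z:.10f}"
        )
    lines.append("")
    lines.append("Bonds")
    lines.append("")
    for n, (i, j) in enumerate(zip(system.bond_i, system.bond_j), start=1):
        lines.append(f"{n} 1 {int(i) + 1} {int(j) + 1}")
    lines.append("")
    Path(path).write_text("\n".join(lines))


def read_data_file(path: str | Path) -> dict:
    """Parse the exported data file back into arrays (nm / amu / e units)."""
    text = Path(path).read_text().splitlines()
    n_atoms = n_bonds = None
    box = np.zeros(3)
    masses, atoms, bonds = {}, [], []
    section = None
    for raw in text:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if line.endswith("atoms"):
            n_atoms = int(line.split()[0]); continue
        if line.endswith("bonds"):
            n_bonds = int(line.split()[0]); continue
        if "atom types" in line or "bond types" in line:
            continue
        if line.endswith(("xlo xhi", "ylo yhi", "zlo zhi")):
            parts = line.split()
            axis = {"xlo": 0, "ylo": 1, "zlo": 2}[parts[2]]
            box[axis] = float(parts[1]) - float(parts[0])
            continue
        if line in ("Masses", "Atoms", "Bonds"):
            section = line
            continue
        parts = line.split()
        if section == "Masses":
            masses[int(parts[0])] = float(parts[1])
        elif section == "Atoms":
            atoms.append(
                (int(parts[0]), int(parts[1]), int(parts[2]), float(parts[3]),
                 float(parts[4]), float(parts[5]), float(parts[6]))
            )
        elif section == "Bonds":
            bonds.append((int(parts[2]), int(parts[3])))
    if n_atoms is None or len(atoms) != n_atoms:
        raise LammpsFormatError("atom count mismatch in data file")
    if n_bonds is None or len(bonds) != n_bonds:
        raise LammpsFormatError("bond count mismatch in data file")
    atoms.sort(key=lambda a: a[0])
    coords = np.array([[a[4], a[5], a[6]] for a in atoms]) / NM_TO_ANGSTROM
    return {
        "coords": coords,
        "box": box / NM_TO_ANGSTROM,
        "charges": np.array([a[3] for a in atoms]),
        "types": np.array([a[2] for a in atoms], dtype=int),
        "molecules": np.array([a[1] for a in atoms], dtype=int),
        "masses": masses,
        "bonds": np.array(bonds, dtype=int) - 1,
    }


def write_pair_tables(
    path: str | Path,
    system: SimSystem,
    forcefield: ForceField,
    protocol: Protocol,
) -> list[str]:
    """Keyed LAMMPS table file, one section per distinct residue-type pair.

    Energies at the nodes equal the analytic potential exactly; a
    midpoint check bounds the linear-interpolation error at 1e-4 kcal/mol
    outside the steep hard core (r >= 0.8 sigma).
    """
    names = []
    chunks = []
    codes = system.type_codes
    for a in range(len(codes)):
        for b in range(a, len(codes)):
            spec = forcefield.pair_spec(system.temperature, codes[a], codes[b])
            cutoff = spec.R
            r = np.linspace(protocol.table_inner_nm, cutoff, protocol.table_points)
            e, f = _pair_table(spec, r)
            mid = 0.5 * (r[:-1] + r[1:])
            interp = 0.5 * (e[:-1] + e[1:])
            # fidelity bound applies outside the steep hard core, where the
            # interpolation error is physically meaningful
            soft = mid >= 0.8 * spec.sigma
            err = np.max(np.abs(interp - pair_potential(mid, spec))[soft])
            if err > 1e-4:
                raise LammpsFormatError(
                    f"table resolution too coarse for pair {codes[a]}:{codes[b]} "
                    f"(interpolation error {err:.2e} kcal/mol)"
                )
            name = _pair_key(codes[a], codes[b])
            names.append(name)
            rows = "\n".join(
                f"{k + 1} {rv * NM_TO_ANGSTROM:.13f} {ev:.14e} {fv / NM_TO_ANGSTROM:.14e}"
                for k, (rv, ev, fv) in enumerate(zip(r, e, f))
            )
            chunks.append(
                f"# pair {codes[a]}-{codes[b]} eps={spec.eps:.6f} kcal/mol "
                f"sigma={spec.sigma:.4f} nm T={system.temperature:.2f} K\n"
                f"{name}\nN {protocol.table_points}\n\n{rows}\n"
            )
    Path(path).write_text("\n".join(chunks))
    return names


def read_pair_table(path: str | Path, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Read one keyed section back; returns (energy kcal/mol, force kcal/mol/nm)
    with distances converted to nm in the first output column triple."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip() == name)
    except StopIteration:
        raise LammpsFormatError(f"section {name!r} not found in {path}")
    n = int(lines[start + 1].split()[1])
    rows = []
    for line in lines[start + 2 :]:
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if not parts[0].isdigit():
            break
        rows.append((float(parts[1]), float(parts[2]), float(parts[3])))
        if len(rows) == n:
            break
    if len(rows) != n:
        raise LammpsFormatError(f"section {name!r}: expected {n} rows, got {len(rows)}")
    arr = np.asarray(rows)
    r = arr[:, 0] / NM_TO_ANGSTROM
    return np.column_stack([r, arr[:, 1]]), arr[:, 2] * NM_TO_ANGSTROM


def write_input_script(
    path: str | Path,
    data_file: str,
    table_file: str,
    pair_names: list[str],
    system: SimSystem,
    protocol: Protocol,
    seed: int = 1,
) -> None:
    codes = system.type_codes
    pair_lines = []
    k = 0
    for a in range(len(codes)):
        for b in range(a, len(codes)):
            cutoff_A = system.pair_R[a, b] * NM_TO_ANGSTROM
            pair_lines.append(
                f"pair_coeff {a + 1} {b + 1} {table_file} {pair_names[k]} {cutoff_A:.4f}"
            )
            k += 1
    bin_A = protocol.bin_width_nm * NM_TO_ANGSTROM
    profile_every = int(round(protocol.profile_every_ns * 1e6 / protocol.timestep_fs))
    damp_fs = protocol.damping_ps * 1000.0
    # harmonic constant: LAMMPS convention U = K (r - r0)^2, ours U = k/2 dr^2
    k_lammps = 0.5 * float(system.bond_k[0]) / NM_TO_ANGSTROM**2
    r0_A = float(system.bond_r0[0]) * NM_TO_ANGSTROM
    script = f"""# slab protocol export (units real)
units real
atom_style full
boundary p p p

read_data {data_file}

bond_style harmonic
bond_coeff 1 {k_lammps:.6f} {r0_A:.4f}

pair_style table linear {protocol.table_points}
{chr(10).join(pair_lines)}

neighbor 3.5 bin
neigh_modify every 10 delay 0 check yes

timestep {protocol.timestep_fs}

velocity all create {system.temperature:.2f} {seed} dist gaussian
fix 1 all nve
fix 2 all langevin {system.temperature:.2f} {system.temperature:.2f} {damp_fs:.1f} {seed}

# z-density profile every {protocol.profile_every_ns} ns (mass density, g/cm^3)
compute zchunk all chunk/atom bin/1d z lower {bin_A:.2f} units box
fix zprof all ave/chunk {profile_every} 1 {profile_every} zchunk density/mass file profile_z.dat

thermo 10000

# equilibration {protocol.equilibration_ns} ns
run {protocol.equilibration_steps}
# production {protocol.production_ns} ns
run {protocol.production_steps}
"""
    Path(path).write_text(script)


def write_export(
    system: SimSystem,
    forcefield: ForceField,
    outdir: str | Path,
    protocol: Protocol | None = None,
    seed: int = 1,
) -> EngineExport:
    """Write data file, pair tables and input script for a resolved system."""
    protocol = protocol or Protocol()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_file = outdir / "system.data"
    table_file = outdir / "pair_tables.table"
    input_script = outdir / "run.in"
    write_data_file(data_file, system)
    names = write_pair_tables(table_file, system, forcefield, protocol)
    write_input_script(
        input_script, data_file.name, table_file.name, names, system, protocol, seed
    )
    return EngineExport(data_file, table_file, input_script, names)


# ---------------------------------------------------------------------------
# chunk-profile reader
# ---------------------------------------------------------------------------

def read_density_profile(
    path: str | Path,
    temperature: float = 0.0,
    timestep_fs: float = 10.0,
) -> DensityProfile:
    """Parse a ``fix ave/chunk`` z-profile file into a DensityProfile.

    Expected dialect: comment headers, then per-frame blocks of
    ``timestep n_chunks total_count`` followed by ``chunk coord ncount
    density`` rows.  Coordinates (Angstrom under real units) convert to
    nm; the density column (g/cm^3 from density/mass) passes through.
    """
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    centers = None
    k = 0
    body = [l for l in lines if not l.lstrip().startswith("#")]
    frame_no = 0
    while k < len(body):
        header = body[k].split()
        if len(header) != 3:
            raise LammpsFormatError(
                f"malformed frame header at frame {frame_no}: {body[k]!r}"
            )
        step, nchunks = int(header[0]), int(header[1])
        rows = body[k + 1 : k + 1 + nchunks]
        if len(rows) < nchunks:
            raise LammpsFormatError(
                f"truncated profile: frame {frame_no} has {len(rows)} of "
                f"{nchunks} bins"
            )
        arr = np.array([[float(x) for x in row.split()] for row in rows])
        this_centers = arr[:, 1] / NM_TO_ANGSTROM
        if centers is None:
            centers = this_centers
        elif len(this_centers) != len(centers):
            raise LammpsFormatError(
                f"inconsistent bin count at frame {frame_no}"
            )
        frames.append(arr[:, -1])
        times.append(step * timestep_fs * 1e-6)  # ns
        k += 1 + nchunks
        frame_no += 1
    if centers is None:
        raise LammpsFormatError("no frames found in profile file")
    return DensityProfile(
        temperature=temperature,
        bin_centers=centers,
        densities=np.asarray(frames),
        frame_times=np.asarray(times),
    )


def write_density_profile(
    path: str | Path,
    profile: DensityProfile,
    timestep_fs: float = 10.0,
) -> None:
    """Inverse of read_density_profile (synthetic fixtures, round-trips)."""
    out = ["# Chunk-averaged data", "# Timestep Number-of-chunks Total-count",
           "# Chunk Coord1 Ncount density/mass"]
    nbins = len(profile.bin_centers)
    times = (
        profile.frame_times
        if profile.frame_times is not None
        else np.arange(len(profile.densities), dtype=float)
    )
    for f, frame in enumerate(profile.densities):
        step = int(round(times[f] * 1e6 / timestep_fs))
        out.append(f"{step} {nbins} {nbins}")
        for b in range(nbins):
            out.append(
                f"  {b + 1} {profile.bin_centers[b] * NM_TO_ANGSTROM:.6f} "
                f"1 {frame[b]:.10g}"
            )
    Path(path).write_text("\n".join(out) + "\n")
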