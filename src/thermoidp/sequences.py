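"""Sequence handling and bead-chain construction.

Maps protein sequences onto residue-level coarse-grained bead chains: one
bead per residue carrying mass, charge, diameter and a homotypic well
depth, connected by harmonic bonds between consecutive residues.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Residues treated as hydrophobic for temperature scaling purposes.
HYDROPHOBIC_RESIDUES = frozenset("AVILM")


class SequenceError(ValueError):
    """Raised for malformed sequences or missing residue parameters."""


@dataclasses.dataclass(frozen=True)
class ResidueBead:
    """Coarse-grained bead parameters for one amino-acid type.

    Attributes
    ----------
    code : str
        One-letter amino-acid symbol.
    mass : float
        Residue mass in amu.
    charge : float
        Bead charge in elementary-charge units.
    sigma : float
        Bead diameter in nm.
    hydrophobic : bool
        True exactly for {A, V, I, L, M}.
    eps_homotypic : float
        Baseline homotypic well depth (kcal/mol) of the parent model.
    """

    code: str
    mass: float
    charge: float
    sigma: float
    hydrophobic: bool
    eps_homotypic: float

    def __post_init__(self) -> None:
        if self.code not in CANONICAL_RESIDUES:
            raise SequenceError(f"non-canonical residue code {self.code!r}")
        if self.mass <= 0:
            raise SequenceError(f"residue {self.code}: mass must be > 0")
        if self.sigma <= 0:
            raise SequenceError(f"residue {self.code}: sigma must be > 0")
        if self.hydrophobic != (self.code in HYDROPHOBIC_RESIDUES):
            raise SequenceError(
                f"residue {self.code}: hydrophobic flag inconsistent with "
                f"membership in {{A,V,I,L,M}}"
            )


@dataclasses.dataclass(frozen=True)
class Bond:
    i: int
    j: int
    k: float  # kcal/mol/nm^2, U = 0.5 k (r - r0)^2
    r0: float  # nm


@dataclasses.dataclass
class ChainTopology:
    """A bead chain: ordered residue codes plus consecutive harmonic bonds."""

    sequence: str
    bonds: list[Bond]
    beads: list[ResidueBead]

    @property
    def n_beads(self) -> int:
        return len(self.sequence)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def net_charge(self) -> float:
        return sum(b.charge for b in self.beads)

    @property
    def total_mass(self) -> float:
        return sum(b.mass for b in self.beads)


class ResidueTable:
    """Per-residue bead parameters plus chain-level (bond, shape) defaults.

    Loaded from a YAML file mapping each canonical residue to
    ``{mass, charge, sigma, eps_homotypic}`` together with harmonic-bond
    constants, default Wang-Frenkel shape exponents and the histidine
    charge convention.
    """

    def __init__(
        self,
        beads: dict[str, ResidueBead],
        bond_k: float,
        bond_r0: float,
        wf_mu: float = 1.0,
        wf_nu: float = 1.0,
        yukawa_cutoff: float = 3.5,
        provenance: str = "unspecified",
    ) -> None:
        self.beads = beads
        if bond_r0 <= 0:
            raise SequenceError("bond rest length must be > 0")
        self.bond_k = float(bond_k)
        self.bond_r0 = float(bond_r0)
        self.wf_mu = float(wf_mu)
        self.wf_nu = float(wf_nu)
        self.yukawa_cutoff = float(yukawa_cutoff)
        self.provenance = provenance

    def __getitem__(self, code: str) -> ResidueBead:
        try:
            return self.beads[code]
        except KeyError:
            raise SequenceError(f"residue {code!r} missing from parameter table")

    def __contains__(self, code: str) -> bool:
        return code in self.beads

    @classmethod
    def from_yaml(cls, path: str | Path, histidine_charge: float | None = None) -> "ResidueTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        h_charge = raw.get("histidine_charge", 0.0)
        if histidine_charge is not None:
            h_charge = histidine_charge
        beads = {}
        for code, fields in raw["residues"].items():
            charge = float(fields["charge"]) if code != "H" else float(h_charge)
            beads[code] = ResidueBead(
                code=code,
                mass=float(fields["mass"]),
                charge=charge,
                sigma=float(fields["sigma"]),
                hydrophobic=code in HYDROPHOBIC_RESIDUES,
                eps_homotypic=float(fields["eps_homotypic"]),
            )
        bond = raw.get("bond", {})
        wf = raw.get("wang_frenkel", {})
        return cls(
            beads,
            bond_k=float(bond.get("k", 4000.0)),
            bond_r0=float(bond.get("r0", 0.381)),
            wf_mu=float(wf.get("mu", 1.0)),
            wf_nu=float(wf.get("nu", 1.0)),
            yukawa_cutoff=float(raw.get("yukawa_cutoff_nm", 3.5)),
            provenance=raw.get("provenance", "unspecified"),
        )

    def to_yaml(self, path: str | Path) -> None:
        h_charge = self.beads["H"].charge if "H" in self.beads else 0.0
        raw = {
            "provenance": self.provenance,
            "histidine_charge": h_charge,
            "bond": {"k": self.bond_k, "r0": self.bond_r0},
            "wang_frenkel": {"mu": self.wf_mu, "nu": self.wf_nu},
            "yukawa_cutoff_nm": self.yukawa_cutoff,
            "residues": {
                code: {
                    "mass": b.mass,
                    "charge": b.charge,
                    "sigma": b.sigma,
                    "eps_homotypic": b.eps_homotypic,
                }
                for code, b in sorted(self.beads.items())
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def validate_sequence(sequence: str) -> str:
    """Uppercase and validate a one-letter sequence; report bad positions."""
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"illegal residue symbol {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, sequence), ...]``.

    Sequences are uppercased and validated against the 20 canonical
    amino acids; the first offending symbol is reported with its position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        try:
            out.append((rec.id, validate_sequence(str(rec.seq))))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(validate_sequence(seq)), id=name, description="")
        for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def build_chain(sequence: str, params: ResidueTable) -> ChainTopology:
    """Map a sequence to a bead chain with length-1 consecutive bonds."""
    seq = validate_sequence(sequence)
    beads = [params[code] for code in seq]
    bonds = [
        Bond(i, i + 1, params.bond_k, params.bond_r0)
        for i in range(len(seq) - 1)
    ]
    return ChainTopology(sequence=seq, bonds=bonds, beads=beads)
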