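"""Protein structure model: PDB reading and building-block decomposition.

A protein is partitioned into *building blocks* — per residue one backbone
unit and one side-chain unit, plus a single N-terminal (-NH3+) and a single
C-terminal (-COO-) block per chain.  Every atom belongs to exactly one block.
Point charges are later placed at each block's charge centre, the
atomic-number-weighted centroid of its atoms (masses replaced by atomic
numbers).

Environment sites (Na+, Cl-, water) are read from HETATM records and carried
separately; each water is represented by a single polarizable site at its
oxygen position.

The input must already be protonated: the ion-binding criteria operate on
H...Cl distances, so hydrogens on basic ionizable groups are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .constants import (
    CL_POLARIZABILITY,
    NA_POLARIZABILITY,
    WATER_POLARIZABILITY,
)
from .residues import (
    AMINO_ACIDS,
    BASIC_SIDECHAINS,
    IONIZABLE_SIDECHAINS,
    SIDECHAIN_ATOMS,
    element_of,
)

__all__ = [
    "Atom",
    "BuildingBlock",
    "ProteinStructure",
    "EnvironmentSite",
    "StructureError",
    "charge_centre",
    "decompose_blocks",
    "read_structure",
]

# Atom names claimed by backbone / terminal blocks.
_BACKBONE_N = ("N",)
_AMIDE_H = ("H", "HN")
_NTER_H = ("H1", "H2", "H3", "HT1", "HT2", "HT3") + _AMIDE_H
_BACKBONE_CA = ("CA", "HA", "HA1", "HA2", "HA3")
_BACKBONE_C = ("C", "O")
_CTER_O = ("OXT", "OT1", "OT2")

_WATER_NAMES = {"HOH", "TIP3", "WAT", "SPC", "TIP"}
_NA_NAMES = {"NA", "SOD"}
_CL_NAMES = {"CL", "CLA"}


class StructureError(ValueError):
    """Raised for malformed or unsupported structure input."""


@dataclass(frozen=True)
class Atom:
    element: str
    atomic_number: int
    coords: np.ndarray  # angstrom
    name: str
    residue_id: tuple[str, int, str]  # (chain, resseq, insertion code)

    def __post_init__(self):
        if self.atomic_number < 1:
            raise StructureError(f"atom {self.name}: atomic number must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")


@dataclass
class BuildingBlock:
    """A contiguous atom group carrying database dipole/polarizability."""

    block_id: str
    residue_name: str
    kind: str  # backbone | sidechain | NTER | CTER
    atoms: list[Atom]
    db_key: str
    charge_centre: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.atoms:
            raise StructureError(f"block {self.block_id} has no atoms")
        self.charge_centre = charge_centre(self.atoms)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"block {self.block_id} has no atom {name!r}")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return self.atoms[0].residue_id


@dataclass
class ProteinStructure:
    blocks: list[BuildingBlock]
    ionizable_sites: list[tuple[str, str]]  # (block_id, group)
    sequence: list[tuple[str, int, str, str]]  # (chain, resseq, icode, resname)

    def block(self, block_id: str) -> BuildingBlock:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)

    @property
    def atoms(self) -> list[Atom]:
        return [a for b in self.blocks for a in b.atoms]


@dataclass
class EnvironmentSite:
    kind: str  # NA | CL | WATER
    coords: np.ndarray  # angstrom (water: oxygen position)
    polarizability: np.ndarray  # 3x3, bohr^3
    charge: float  # e

    def __post_init__(self):
        a = np.asarray(self.polarizability, dtype=float)
        if not np.allclose(a, a.T, atol=1e-10):
            raise StructureError("environment-site polarizability must be symmetric")
        if np.linalg.eigvalsh(a).min() < -1e-10:
            raise StructureError("environment-site polarizability must be PSD")


def charge_centre(atoms: list[Atom] | BuildingBlock) -> np.ndarray:
    """Atomic-number-weighted centroid: sum(Z_i r_i) / sum(Z_i), in angstrom."""
    if isinstance(atoms, BuildingBlock):
        atoms = atoms.atoms
    z = np.array([a.atomic_number for a in atoms], dtype=float)
    r = np.array([a.coords for a in atoms], dtype=float)
    return (z[:, None] * r).sum(axis=0) / z.sum()


def _block_id(chain: str, resseq: int, icode: str, kind: str) -> str:
    return f"{chain}:{resseq}{icode.strip()}:{kind}"


def decompose_blocks(
    residues: list[tuple[str, tuple[str, int, str], list[Atom]]],
) -> list[BuildingBlock]:
    """Split one chain's residues into backbone/side-chain/terminal blocks.

    ``residues`` is an ordered list of ``(resname, residue_id, atoms)`` for a
    single chain.  The first residue's -NH3+ atoms form the NTER block and the
    last residue's -COO- atoms form the CTER block; every remaining atom goes
    to its residue's backbone or side-chain block (GLY has no side chain).
    """
    if len(residues) < 2:
        raise StructureError("a chain needs at least 2 residues (NTER and CTER)")
    blocks: list[BuildingBlock] = []
    last = len(residues) - 1
    for i, (resname, rid, atoms) in enumerate(residues):
        if resname not in AMINO_ACIDS:
            raise StructureError(f"unknown residue name {resname!r} at {rid}")
        chain, resseq, icode = rid
        by_name: dict[str, Atom] = {}
        for a in atoms:
            by_name[a.name] = a
        claimed: set[str] = set()

        def take(names) -> list[Atom]:
            got = [by_name[n] for n in names if n in by_name and n not in claimed]
            claimed.update(a.name for a in got)
            return got

        if i == 0:
            nter = take(_BACKBONE_N + _NTER_H)
            if nter:
                blocks.append(BuildingBlock(
                    _block_id(chain, resseq, icode, "NTER"),
                    resname, "NTER", nter, "NTER"))
            bb = take(_BACKBONE_CA + _BACKBONE_C)
            key = f"{resname}:backbone_nter"
        elif i == last:
            bb = take(_BACKBONE_N + _AMIDE_H + _BACKBONE_CA)
            key = f"{resname}:backbone_cter"
        else:
            bb = take(_BACKBONE_N + _AMIDE_H + _BACKBONE_CA + _BACKBONE_C)
            key = f"{resname}:backbone"
        if bb:
            blocks.append(BuildingBlock(
                _block_id(chain, resseq, icode, "backbone"),
                resname, "backbone", bb, key))
        cter = take(_BACKBONE_C + _CTER_O) if i == last else []

        side = [a for a in atoms if a.name not in claimed]
        template = SIDECHAIN_ATOMS[resname]
        for a in side:
            if a.name not in template:
                raise StructureError(
                    f"atom {a.name!r} of {resname} {rid} cannot be assigned "
                    f"to any building block")
        if side:
            blocks.append(BuildingBlock(
                _block_id(chain, resseq, icode, "sidechain"),
                resname, "sidechain", side, f"{resname}:sidechain"))
        if cter:
            blocks.append(BuildingBlock(
                _block_id(chain, resseq, icode, "CTER"),
                resname, "CTER", cter, "CTER"))
    return blocks


def _classify_ionizable(blocks: list[BuildingBlock]) -> list[tuple[str, str]]:
    sites = []
    for b in blocks:
        if b.kind == "NTER":
            sites.append((b.block_id, "NTER"))
        elif b.kind == "CTER":
            sites.append((b.block_id, "CTER"))
        elif b.kind == "sidechain" and b.residue_name in IONIZABLE_SIDECHAINS:
            sites.append((b.block_id, b.residue_name))
    return sites


def _check_protonation(blocks: list[BuildingBlock]) -> None:
    """Basic ionizable groups must carry hydrogens (H...Cl criterion)."""
    for b in blocks:
        needs_h = (b.kind == "NTER" or
                   (b.kind == "sidechain" and b.residue_name in BASIC_SIDECHAINS))
        if needs_h and not any(a.element == "H" for a in b.atoms):
            raise StructureError(
                f"ionizable group {b.residue_name} {b.residue_id} has no "
                f"hydrogens; a protonated input structure is required")


def _env_site(kind: str, coords: np.ndarray) -> EnvironmentSite:
    iso = {"NA": NA_POLARIZABILITY, "CL": CL_POLARIZABILITY,
           "WATER": WATER_POLARIZABILITY}[kind]
    q = {"NA": 1.0, "CL": -1.0, "WATER": 0.0}[kind]
    return EnvironmentSite(kind, coords, iso * np.eye(3), q)


def read_structure(pdb_text: str) -> tuple[ProteinStructure, list[EnvironmentSite]]:
    """Parse PDB text into a block-decomposed protein plus environment sites.

    Deterministic ordering: chains in file order, residues by sequence number,
    blocks NTER -> backbone -> sidechain -> CTER within a residue.  For
    alternate conformations the highest-occupancy conformer is kept.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no models in PDB input")
    model = st[0]

    blocks: list[BuildingBlock] = []
    env: list[EnvironmentSite] = []
    sequence: list[tuple[str, int, str, str]] = []
    for chain in model:
        chain_residues: list[tuple[str, tuple[str, int, str], list[Atom]]] = []
        for res in chain:
            name = res.name.strip().upper()
            rid = (chain.name, res.seqid.num, res.seqid.icode.strip())
            # keep the highest-occupancy alternate conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            if name in _WATER_NAMES:
                oxy = [a for a in best.values()
                       if element_of(a.name, name) == "O"]
                if not oxy:
                    raise StructureError(f"water {rid} has no oxygen atom")
                p = oxy[0].pos
                env.append(_env_site("WATER", np.array([p.x, p.y, p.z])))
            elif name in _NA_NAMES or name in _CL_NAMES:
                kind = "NA" if name in _NA_NAMES else "CL"
                for at in best.values():
                    p = at.pos
                    env.append(_env_site(kind, np.array([p.x, p.y, p.z])))
            elif name in AMINO_ACIDS:
                atoms = []
                for at in best.values():
                    elem = at.element.name if at.element.name != "X" \
                        else element_of(at.name, name)
                    zn = gemmi.Element(elem).atomic_number
                    atoms.append(Atom(elem, zn,
                                      np.array([at.pos.x, at.pos.y, at.pos.z]),
                                      at.name, rid))
                atoms.sort(key=lambda a: a.name)
                chain_residues.append((name, rid, atoms))
                sequence.append((chain.name, res.seqid.num,
                                 res.seqid.icode.strip(), name))
            else:
                raise StructureError(f"unknown residue name {name!r} at {rid}")
        if chain_residues:
            chain_residues.sort(key=lambda r: (r[1][1], r[1][2]))
            blocks.extend(decompose_blocks(chain_residues))

    _check_protonation(blocks)
    structure = ProteinStructure(blocks, _classify_ionizable(blocks), sequence)
    _assert_partition(structure, model)
    return structure, env


def _assert_partition(structure: ProteinStructure, model: gemmi.Model) -> None:
    """Every protein atom ends up in exactly one block."""
    n_protein = 0
    for chain in model:
        for res in chain:
            if res.name.strip().upper() in AMINO_ACIDS:
                seen = set()
                for at in res:
                    if at.name not in seen:  # altloc duplicates collapse
                        seen.add(at.name)
                        n_protein += 1
    n_blocks = sum(len(b.atoms) for b in structure.blocks)
    if n_blocks != n_protein:
        raise StructureError(
            f"block decomposition lost atoms: {n_blocks} != {n_protein}")
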