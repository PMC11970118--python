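"""Amino-acid residue vocabulary: atom-name templates and element inference.

Atom names follow PDB v3 conventions for the heavy atoms and a CHARMM-like
scheme for hydrogens (HB1/HB2 rather than 1HB/2HB).  The side-chain templates
list every atom that is *not* part of the peptide backbone; the backbone
itself (N, H, CA, HA, C, O plus terminal variants) is handled by
:mod:`blockpol.structure_model`.
"""

from __future__ import annotations

#: Side-chain atom names per residue, in a fixed canonical order
#: (heavy atoms interleaved with their hydrogens, walking outward from CB).
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB", "HB1", "HB2", "HB3"),
    "ARG": ("CB", "HB1", "HB2", "CG", "HG1", "HG2", "CD", "HD1", "HD2",
            "NE", "HE", "CZ", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22"),
    "ASN": ("CB", "HB1", "HB2", "CG", "OD1", "ND2", "HD21", "HD22"),
    "ASP": ("CB", "HB1", "HB2", "CG", "OD1", "OD2"),
    "CYS": ("CB", "HB1", "HB2", "SG", "HG1"),
    "GLN": ("CB", "HB1", "HB2", "CG", "HG1", "HG2", "CD", "OE1",
            "NE2", "HE21", "HE22"),
    "GLU": ("CB", "HB1", "HB2", "CG", "HG1", "HG2", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "HB1", "HB2", "CG", "ND1", "HD1", "CD2", "HD2",
            "CE1", "HE1", "NE2"),
    "ILE": ("CB", "HB", "CG1", "HG11", "HG12", "CG2", "HG21", "HG22", "HG23",
            "CD1", "HD11", "HD12", "HD13"),
    "LEU": ("CB", "HB1", "HB2", "CG", "HG", "CD1", "HD11", "HD12", "HD13",
            "CD2", "HD21", "HD22", "HD23"),
    "LYS": ("CB", "HB1", "HB2", "CG", "HG1", "HG2", "CD", "HD1", "HD2",
            "CE", "HE1", "HE2", "NZ", "HZ1", "HZ2", "HZ3"),
    "MET": ("CB", "HB1", "HB2", "CG", "HG1", "HG2", "SD",
            "CE", "HE1", "HE2", "HE3"),
    "PHE": ("CB", "HB1", "HB2", "CG", "CD1", "HD1", "CD2", "HD2",
            "CE1", "HE1", "CE2", "HE2", "CZ", "HZ"),
    "PRO": ("CB", "HB1", "HB2", "CG", "HG1", "HG2", "CD", "HD1", "HD2"),
    "SER": ("CB", "HB1", "HB2", "OG", "HG1"),
    "THR": ("CB", "HB", "OG1", "HG1", "CG2", "HG21", "HG22", "HG23"),
    "TRP": ("CB", "HB1", "HB2", "CG", "CD1", "HD1", "CD2", "NE1", "HE1",
            "CE2", "CE3", "HE3", "CZ2", "HZ2", "CZ3", "HZ3", "CH2", "HH2"),
    "TYR": ("CB", "HB1", "HB2", "CG", "CD1", "HD1", "CD2", "HD2",
            "CE1", "HE1", "CE2", "HE2", "CZ", "OH", "HH"),
    "VAL": ("CB", "HB", "CG1", "HG11", "HG12", "HG13",
            "CG2", "HG21", "HG22", "HG23"),
}

AMINO_ACIDS = frozenset(SIDECHAIN_ATOMS)

#: Residues whose side chain (or terminal group) titrates, with the sign of
#: the fully ionized species.
ACIDIC_SIDECHAINS = frozenset({"ASP", "GLU", "CYS", "TYR"})
BASIC_SIDECHAINS = frozenset({"ARG", "LYS", "HIS"})
IONIZABLE_SIDECHAINS = ACIDIC_SIDECHAINS | BASIC_SIDECHAINS

#: A 29-residue sequence with glucagon's ionizable composition: one HIS,
#: three ASP, two TYR, one LYS, two ARG plus the two termini.
GLUCAGON_SEQUENCE: tuple[str, ...] = (
    "HIS", "SER", "GLN", "GLY", "THR", "PHE", "THR", "SER", "ASP", "TYR",
    "SER", "LYS", "TYR", "LEU", "ASP", "SER", "ARG", "ARG", "ALA", "GLN",
    "ASP", "PHE", "VAL", "GLN", "TRP", "LEU", "MET", "ASN", "THR",
)

_TWO_LETTER_ELEMENTS = {"NA", "CL", "MG", "ZN", "FE", "BR", "CA"}


def element_of(atom_name: str, residue_name: str = "") -> str:
    """Infer the chemical element from a PDB atom name.

    Protein atom names start with the element letter (C, N, O, S, H);
    monatomic-ion HETATM names (NA, CL) are recognized via the residue name.
    """
    name = atom_name.strip().upper()
    if residue_name.strip().upper() in _TWO_LETTER_ELEMENTS and name == residue_name.strip().upper():
        return name.capitalize()
    # strip any leading digits (e.g. "1HB")
    core = name.lstrip("0123456789")
    if not core:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return core[0]


def heavy_atom_count(names: tuple[str, ...] | list[str]) -> int:
    """Number of non-hydrogen atoms in a list of atom names."""
    return sum(1 for n in names if element_of(n) != "H")
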