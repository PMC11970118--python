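"""Synthetic toy-peptide structures for tests, demos and benchmarks.

``make_fixture`` emits protonated PDB text for an ideal-geometry alpha-helix
(canonical rise 1.5 A and 100 degrees twist per residue), optionally with
Na+/Cl- ions placed at controlled distances from ionizable side chains and a
loose water shell.  The side-chain geometry is schematic — atoms walk outward
from C-alpha with deterministic offsets — which is sufficient for everything
this package computes from a structure: block decomposition, charge centres,
local frames and ion-coordination distances.  It is *not* chemically accurate
geometry and is labelled synthetic on output.
"""

from __future__ import annotations

import math

import gemmi
import numpy as np

from .residues import AMINO_ACIDS, SIDECHAIN_ATOMS, element_of

__all__ = ["make_fixture", "acidic_anchor_atoms", "basic_anchor_atoms"]

_RISE = 1.5       # A per residue
_TWIST = 100.0    # degrees per residue
_RADIUS = 2.3     # C-alpha helix radius, A

_DEFAULT_PATTERN = ("ALA", "SER", "LEU", "THR", "GLY")


def _salt_sequence(n: int) -> tuple[str, ...]:
    """Charge-separated salt-fixture sequence: basic groups near the
    N-terminal end, acidic groups near the C-terminal end.

    The spatial separation gives the peptide a large charge dipole moment,
    which neutralizing bound ion pairs then reduces — the arrangement used
    to study how salting in/out shifts the dipole.  For n >= 12 the sequence
    has three basic and three acidic side chains, so with the two termini it
    offers the full four Na+ and four Cl- coordination sites.
    """
    seq = [_DEFAULT_PATTERN[i % len(_DEFAULT_PATTERN)] for i in range(n)]
    if n >= 12:
        for idx, res in zip((1, 3, 5), ("LYS", "ARG", "LYS")):
            seq[idx] = res
        for idx, res in zip((n - 6, n - 4, n - 2), ("ASP", "GLU", "ASP")):
            seq[idx] = res
    else:
        seq[1] = "LYS"
        seq[n - 2] = "ASP"
    return tuple(seq)

#: Outermost hydrogen used as the Cl- coordination anchor per basic group
#: (HIS is not a Cl- binding group and gets no placed ion).
BASIC_ANCHOR_H = {"LYS": "HZ3", "ARG": "HH22", "NTER": "H1"}
#: Outermost carboxylate oxygen used as the Na+ coordination anchor.
ACIDIC_ANCHOR_O = {"ASP": "OD2", "GLU": "OE2", "CTER": "OXT"}


def acidic_anchor_atoms():
    return dict(ACIDIC_ANCHOR_O)


def basic_anchor_atoms():
    return dict(BASIC_ANCHOR_H)


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tripod(apex: np.ndarray, away: np.ndarray, ref: np.ndarray,
            bond: float = 1.02) -> list[np.ndarray]:
    """Three points around ``apex`` pointing away from the ``away`` direction."""
    axis = _normalize(away)
    p1 = ref - (ref @ axis) * axis
    p1 = _normalize(p1) if np.linalg.norm(p1) > 1e-8 else _normalize(
        np.cross(axis, [1.0, 0.0, 0.0]))
    p2 = np.cross(axis, p1)
    out = []
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        d = _normalize(-axis + 1.4 * (math.cos(ang) * p1 + math.sin(ang) * p2))
        out.append(apex + bond * d)
    return out


def _chain_atoms(sequence: tuple[str, ...]) -> list[list[tuple[str, np.ndarray]]]:
    """Per-residue named coordinates for one helical chain."""
    n = len(sequence)
    ca = np.array([
        [_RADIUS * math.cos(math.radians(_TWIST * i)),
         _RADIUS * math.sin(math.radians(_TWIST * i)),
         _RISE * i] for i in range(n)])
    residues = []
    for i, resname in enumerate(sequence):
        t = _normalize(ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)])
        rad = _normalize(np.array([ca[i][0], ca[i][1], 0.0]))
        nrm = _normalize(np.cross(t, rad))
        atoms: list[tuple[str, np.ndarray]] = []
        npos = ca[i] - 1.46 * _normalize(t + 0.45 * nrm)
        cpos = ca[i] + 1.52 * _normalize(t - 0.45 * nrm)
        atoms.append(("N", npos))
        if i == 0:
            for k, h in enumerate(_tripod(npos, npos - ca[i], nrm)):
                atoms.append((f"H{k + 1}", h))
        else:
            atoms.append(("H", npos + 1.0 * _normalize(nrm - 0.4 * t)))
        atoms.append(("CA", ca[i]))
        if resname == "GLY":
            atoms.append(("HA1", ca[i] + 1.09 * _normalize(-nrm + 0.2 * t)))
            atoms.append(("HA2", ca[i] + 1.09 * rad))
        else:
            atoms.append(("HA", ca[i] + 1.09 * _normalize(-nrm + 0.2 * t)))
        atoms.append(("C", cpos))
        atoms.append(("O", cpos + 1.23 * _normalize(nrm - 0.3 * t)))
        if i == n - 1:
            atoms.append(("OXT", cpos + 1.25 * _normalize(t + 0.5 * rad)))
        for k, name in enumerate(SIDECHAIN_ATOMS[resname]):
            pos = (ca[i] + rad * (1.2 + 0.55 * k)
                   + nrm * 0.4 * math.sin(2.1 * k)
                   + t * 0.3 * math.cos(1.7 * k))
            atoms.append((name, pos))
        residues.append(atoms)
    return residues


def _anchor_sites(sequence, residues):
    """(kind, anchor position, push-away reference) for acidic/basic groups.

    Ions are later placed at a controlled distance from the anchor atom along
    the direction pointing away from the reference atom, which keeps the
    anchor the closest atom of its group.
    """
    coords = [dict(r) for r in residues]
    acidic, basic = [], []
    for i, resname in enumerate(sequence):
        if resname in ("ASP", "GLU"):
            acidic.append(("NA", coords[i][ACIDIC_ANCHOR_O[resname]],
                           coords[i]["CA"]))
        if resname in ("LYS", "ARG"):
            basic.append(("CL", coords[i][BASIC_ANCHOR_H[resname]],
                          coords[i]["CA"]))
    acidic.append(("NA", coords[-1][ACIDIC_ANCHOR_O["CTER"]], coords[-1]["C"]))
    basic.append(("CL", coords[0][BASIC_ANCHOR_H["NTER"]], coords[0]["N"]))
    return acidic, basic


def make_fixture(kind: str, n_residues: int, seed: int = 0, *,
                 sequence: tuple[str, ...] | None = None,
                 pairs: int | None = None,
                 na_distance: float = 3.4,
                 cl_distance: float = 2.4,
                 n_waters: int = 0,
                 water_shell: float = 6.0) -> str:
    """Build a synthetic protonated PDB fixture.

    Parameters
    ----------
    kind : "helix" (bare peptide), "dimer" (two copies, chains A and B) or
        "saltbox" (helix plus NaCl pairs coordinated to ionizable groups).
    n_residues : residues per chain (>= 2).
    seed : controls water placement; the peptide geometry is seed-independent.
    sequence : optional explicit residue sequence (overrides the default
        repeating pattern; pass
        :data:`blockpol.residues.GLUCAGON_SEQUENCE` for a glucagon-like
        ionizable composition).  The default "saltbox" sequence separates
        basic and acidic groups to the two helix ends.
    pairs : number of NaCl pairs for "saltbox" (default: as many as the
        ionizable composition supports, at most 4).  Na+ sits ``na_distance``
        (A) outward from a carboxylate O, Cl- ``cl_distance`` outward from a
        basic-group H, so default distances fall inside the binding
        thresholds.
    n_waters : waters placed on a loose shell around the peptide.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if kind not in {"helix", "dimer", "saltbox"}:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if sequence is None:
        if kind == "saltbox":
            sequence = _salt_sequence(n_residues)
        else:
            sequence = tuple(_DEFAULT_PATTERN[i % len(_DEFAULT_PATTERN)]
                             for i in range(n_residues))
    sequence = tuple(s.upper() for s in sequence)
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    bad = [s for s in sequence if s not in AMINO_ACIDS]
    if bad:
        raise ValueError(f"unknown residues in sequence: {bad}")

    rng = np.random.default_rng(seed)
    chains = [("A", _chain_atoms(sequence))]
    if kind == "dimer":
        shifted = [[(nm, pos + np.array([25.0, 0.0, 0.0])) for nm, pos in res]
                   for res in chains[0][1]]
        chains.append(("B", shifted))

    ions: list[tuple[str, np.ndarray]] = []
    if kind == "saltbox":
        acidic, basic = _anchor_sites(sequence, chains[0][1])
        n_pairs = min(len(acidic), len(basic), 4) if pairs is None else pairs
        if n_pairs > min(len(acidic), len(basic)):
            raise ValueError(
                f"requested {n_pairs} pairs but fixture has only "
                f"{len(acidic)} acidic / {len(basic)} basic anchors")
        for (_, opos, oref), (_, hpos, href) in zip(acidic[:n_pairs],
                                                    basic[:n_pairs]):
            ions.append(("NA", opos + na_distance * _normalize(opos - oref)))
            ions.append(("CL", hpos + cl_distance * _normalize(hpos - href)))

    waters: list[np.ndarray] = []
    if n_waters:
        protein = np.array([p for _, res in chains for r in res for _, p in r])
        centre = protein.mean(axis=0)
        rmax = np.linalg.norm(protein - centre, axis=1).max()
        for _ in range(n_waters):
            d = _normalize(rng.normal(size=3))
            waters.append(centre + d * (rmax + rng.uniform(1.0, water_shell)))

    return _write_pdb(sequence, chains, ions, waters)


def _write_pdb(sequence, chains, ions, waters) -> str:
    st = gemmi.Structure()
    st.name = "blockpol synthetic fixture"
    model = gemmi.Model("1")
    for chain_name, residues in chains:
        ch = gemmi.Chain(chain_name)
        for i, atoms in enumerate(residues):
            res = gemmi.Residue()
            res.name = sequence[i]
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            for name, pos in atoms:
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(element_of(name, sequence[i]))
                at.pos = gemmi.Position(*pos)
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)

    if ions or waters:
        ch = gemmi.Chain("S")
        num = 1
        for ion_kind, pos in ions:
            res = gemmi.Residue()
            res.name = ion_kind
            res.seqid = gemmi.SeqId(num, " ")
            res.het_flag = "H"
            at = gemmi.Atom()
            at.name = ion_kind
            at.element = gemmi.Element(ion_kind.capitalize())
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            at.charge = 1 if ion_kind == "NA" else -1
            res.add_atom(at)
            ch.add_residue(res)
            num += 1
        for opos in waters:
            res = gemmi.Residue()
            res.name = "HOH"
            res.seqid = gemmi.SeqId(num, " ")
            res.het_flag = "H"
            for name, off in (("O", (0.0, 0.0, 0.0)),
                              ("H1", (0.96, 0.0, 0.0)),
                              ("H2", (-0.24, 0.93, 0.0))):
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(element_of(name))
                at.pos = gemmi.Position(*(opos + np.array(off)))
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
            num += 1
        model.add_chain(ch)

    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
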