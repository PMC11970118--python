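"""Per-block property database: dipole vectors and polarizability tensors.

Each entry stores, in a *local* frame anchored on three named atoms of the
block, a permanent (core) dipole vector in e.bohr and a symmetric
positive-semidefinite polarizability tensor in bohr^3.  Placing an entry onto
a concrete building block rotates both into the global frame; a rotation
preserves the tensor eigenvalues, which is what makes the properties
transferable between copies of the same chemical group.

Because no published per-residue entries ship with this package, a synthetic
database generator is provided.  Its tensors are random but physically shaped
(SPD, isotropic average proportional to the heavy-atom count) and fully
reproducible from a seed; it exercises the full vector/tensor pipeline
without pretending to be fitted data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .residues import AMINO_ACIDS, SIDECHAIN_ATOMS, heavy_atom_count
from .structure_model import BuildingBlock

__all__ = [
    "BlockEntry",
    "BlockDB",
    "DatabaseError",
    "load_db",
    "save_db",
    "synthesize_db",
    "place_entry",
]

SCHEMA_VERSION = "blockpol-db-1"


class DatabaseError(ValueError):
    """Raised for malformed database files or entries."""


def _round12(x: float) -> float:
    """Round to 12 significant digits (the database's on-disk precision)."""
    return float(f"{float(x):.12g}")


@dataclass
class BlockEntry:
    db_key: str
    dipole_local: np.ndarray          # 3-vector, e.bohr
    polarizability_local: np.ndarray  # 3x3 symmetric PSD, bohr^3
    frame_atoms: tuple[str, str, str]

    def __post_init__(self):
        self.dipole_local = np.asarray(self.dipole_local, dtype=float)
        a = np.asarray(self.polarizability_local, dtype=float)
        self.polarizability_local = a
        if self.dipole_local.shape != (3,):
            raise DatabaseError(f"{self.db_key}: dipole must be a 3-vector")
        if a.shape != (3, 3):
            raise DatabaseError(f"{self.db_key}: polarizability must be 3x3")
        if not np.array_equal(a, a.T):
            raise DatabaseError(
                f"{self.db_key}: polarizability tensor is not symmetric")
        if np.linalg.eigvalsh(a).min() < -1e-10:
            raise DatabaseError(
                f"{self.db_key}: polarizability has negative eigenvalues")
        if len(set(self.frame_atoms)) != 3:
            raise DatabaseError(f"{self.db_key}: frame atoms must be distinct")

    def __eq__(self, other):
        return (isinstance(other, BlockEntry)
                and self.db_key == other.db_key
                and np.array_equal(self.dipole_local, other.dipole_local)
                and np.array_equal(self.polarizability_local,
                                   other.polarizability_local)
                and tuple(self.frame_atoms) == tuple(other.frame_atoms))


@dataclass
class BlockDB:
    entries: dict[str, BlockEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=lambda: {"units": "au",
                                                    "version": SCHEMA_VERSION})

    def __getitem__(self, key: str) -> BlockEntry:
        try:
            return self.entries[key]
        except KeyError:
            raise DatabaseError(f"no database entry for block key {key!r}")

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __eq__(self, other):
        return (isinstance(other, BlockDB)
                and self.metadata == other.metadata
                and self.entries == other.entries)


def save_db(db: BlockDB, path) -> None:
    """Write the database as UTF-8 JSON with sorted keys, 12 significant digits."""
    doc = {
        "metadata": db.metadata,
        "entries": {
            k: {
                "dipole_local": [_round12(x) for x in e.dipole_local],
                "polarizability_local": [
                    [_round12(x) for x in row] for row in e.polarizability_local],
                "frame_atoms": list(e.frame_atoms),
            }
            for k, e in db.entries.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_db(path) -> BlockDB:
    """Load and validate a block database; load(save(db)) == db."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise DatabaseError("database file has no 'entries' object")
    entries = {}
    for key, raw in doc["entries"].items():
        missing = {"dipole_local", "polarizability_local", "frame_atoms"} - set(raw)
        if missing:
            raise DatabaseError(f"entry {key!r} is missing fields {sorted(missing)}")
        entries[key] = BlockEntry(
            db_key=key,
            dipole_local=np.array(raw["dipole_local"], dtype=float),
            polarizability_local=np.array(raw["polarizability_local"], dtype=float),
            frame_atoms=tuple(raw["frame_atoms"]),
        )
    return BlockDB(entries=entries, metadata=doc.get("metadata", {}))


# --- synthetic database ----------------------------------------------------

#: (db-key suffix, atom names in the block, frame atoms) per backbone variant.
_BACKBONE_VARIANTS = (
    ("backbone", ("N", "H", "CA", "HA", "C", "O"), ("N", "CA", "C")),
    ("backbone_nter", ("CA", "HA", "C", "O"), ("CA", "C", "O")),
    ("backbone_cter", ("N", "H", "CA", "HA"), ("N", "CA", "HA")),
)
_TERMINAL_ENTRIES = (
    ("NTER", ("N", "H1", "H2", "H3"), ("N", "H1", "H2")),
    ("CTER", ("C", "O", "OXT"), ("C", "O", "OXT")),
)


def _random_spd(rng: np.random.Generator, iso: float,
                anisotropy_frac: float) -> np.ndarray:
    """Random symmetric tensor with trace/3 == iso and bounded eigenvalue spread."""
    d = rng.uniform(-1.0, 1.0, 3)
    d = 0.75 * (d - d.mean())          # zero-mean, |d| < 1
    eigs = iso * (1.0 + anisotropy_frac * d)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    a = q @ np.diag(eigs) @ q.T
    a = 0.5 * (a + a.T)
    a = np.array([[_round12(x) for x in row] for row in a])
    return 0.5 * (a + a.T)


def _synthetic_entry(rng: np.random.Generator, key: str, names, frame,
                     base_iso: float, anisotropy_frac: float) -> BlockEntry:
    n_heavy = max(1, heavy_atom_count(names))
    alpha = _random_spd(rng, base_iso * n_heavy, anisotropy_frac)
    mag = _round12(rng.uniform(0.5, 2.0))
    return BlockEntry(key, np.array([mag, 0.0, 0.0]), alpha, tuple(frame))


def synthesize_db(residue_set=None, seed: int = 0, base_iso: float = 10.0,
                  anisotropy_frac: float = 0.3) -> BlockDB:
    """Generate a reproducible synthetic database for the given residues.

    Parameters
    ----------
    residue_set : iterable of 3-letter codes (default: all 20 amino acids)
    seed : RNG seed; the output is a pure function of the arguments.
    base_iso : isotropic polarizability per heavy atom, bohr^3.  The default
        of 10 bohr^3 puts a mid-sized peptide in the low-thousands range
        typical of real proteins.
    anisotropy_frac : relative eigenvalue spread in [0, 1); 0 gives strictly
        isotropic tensors.

    Dipoles point along the first local frame axis with magnitudes drawn
    from U(0.5, 2.0) e.bohr.
    """
    if residue_set is None:
        residue_set = AMINO_ACIDS
    residues = sorted(residue_set)
    unknown = [r for r in residues if r not in AMINO_ACIDS]
    if unknown:
        raise DatabaseError(f"unknown residues {unknown}")
    if base_iso <= 0:
        raise DatabaseError("base_iso must be positive")
    if not 0 <= anisotropy_frac < 1:
        raise DatabaseError("anisotropy_frac must be in [0, 1)")

    rng = np.random.default_rng(seed)
    db = BlockDB(metadata={"units": "au", "version": SCHEMA_VERSION,
                           "seed": int(seed), "base_iso": base_iso,
                           "anisotropy_frac": anisotropy_frac,
                           "synthetic": True})
    for res in residues:
        for suffix, names, frame in _BACKBONE_VARIANTS:
            key = f"{res}:{suffix}"
            if res == "GLY":  # GLY has HA1/HA2 in place of HA
                frame = tuple("HA1" if a == "HA" else a for a in frame)
            db.entries[key] = _synthetic_entry(
                rng, key, names, frame, base_iso, anisotropy_frac)
        side = SIDECHAIN_ATOMS[res]
        if side:
            key = f"{res}:sidechain"
            db.entries[key] = _synthetic_entry(
                rng, key, side, side[:3], base_iso, anisotropy_frac)
    for key, names, frame in _TERMINAL_ENTRIES:
        db.entries[key] = _synthetic_entry(
            rng, key, names, frame, base_iso, anisotropy_frac)
    return db


# --- placement -------------------------------------------------------------

def frame_rotation(r1: np.ndarray, r2: np.ndarray, r3: np.ndarray) -> np.ndarray:
    """Orthonormal frame from three anchor points by Gram-Schmidt.

    Axis 1 points from atom 1 to atom 2; axis 2 is the in-plane component of
    atom1->atom3; axis 3 completes a right-handed triad.  Returns the rotation
    matrix whose *columns* are the global-frame axes (local -> global map).
    """
    e1 = np.asarray(r2, float) - np.asarray(r1, float)
    n1 = np.linalg.norm(e1)
    if n1 < 1e-8:
        raise DatabaseError("frame atoms 1 and 2 coincide")
    e1 = e1 / n1
    v = np.asarray(r3, float) - np.asarray(r1, float)
    v = v - (v @ e1) * e1
    n2 = np.linalg.norm(v)
    if n2 < 1e-8:
        raise DatabaseError("frame atoms are collinear")
    e2 = v / n2
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def place_entry(entry: BlockEntry,
                block: BuildingBlock) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an entry's local dipole and tensor into the block's global frame.

    Returns ``(dipole_global, polarizability_global)``; the tensor keeps its
    eigenvalues (pure rotation).
    """
    anchors = [block.atom(name).coords for name in entry.frame_atoms]
    rot = frame_rotation(*anchors)
    mu = rot @ entry.dipole_local
    alpha = rot @ entry.polarizability_local @ rot.T
    return mu, 0.5 * (alpha + alpha.T)
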