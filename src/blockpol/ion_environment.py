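"""Ion coordination, charge neutralization, water-shell trimming and the
combinatorics of NaCl placement configurations.

A Cl- counts as bound to a basic group (LYS, ARG side chains, the NTER
group) when its shortest distance to any hydrogen of that group is at most
2.5 A; a Na+ counts as bound to a carboxylate group (ASP, GLU side chains,
the CTER group) when its shortest distance to any carboxylate oxygen is at
most 3.5 A.  A bound ion neutralizes its residue for the charge dipole, but
both the ionic charge and the residue charge remain as field sources for the
core-dipole correction.

Because Na+ and Cl- enter in charge-balancing pairs on four acidic (A-D) and
four basic (X, Y, Z, W) sites, there are sum_k C(4,k)^2 = 70 possible
placements: 1 + 16 + 36 + 16 + 1 by pair count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .constants import CL_BIND_THRESHOLD, NA_BIND_THRESHOLD
from .protonation import ChargeSite
from .structure_model import EnvironmentSite, ProteinStructure

__all__ = [
    "IonBinding",
    "IonConfiguration",
    "detect_bound_ions",
    "neutralize",
    "ellipsoid_cutoff",
    "enumerate_configurations",
    "config_name",
]

NA_LETTERS = "ABCD"
CL_LETTERS = "XYZW"

#: Groups a Cl- can coordinate to (via H) and a Na+ can coordinate to (via O).
CL_BINDING_GROUPS = frozenset({"LYS", "ARG", "NTER"})
NA_BINDING_GROUPS = frozenset({"ASP", "GLU", "CTER"})

_CARBOXYLATE_O = frozenset({"OD1", "OD2", "OE1", "OE2", "O", "OXT", "OT1", "OT2"})


@dataclass(frozen=True)
class IonBinding:
    ion_index: int          # index into the ion list passed in
    ion: EnvironmentSite
    residue_block_id: str
    distance: float         # angstrom
    bound: bool = True


@dataclass(frozen=True)
class IonConfiguration:
    na_sites: frozenset
    cl_sites: frozenset
    name: str
    number: int

    @property
    def n_pairs(self) -> int:
        return len(self.na_sites)


def _min_distance(ion_pos: np.ndarray, block, atom_filter) -> float:
    d = [float(np.linalg.norm(a.coords - ion_pos))
         for a in block.atoms if atom_filter(a)]
    return min(d) if d else np.inf


def detect_bound_ions(structure: ProteinStructure,
                      ions: list[EnvironmentSite],
                      cl_threshold: float = CL_BIND_THRESHOLD,
                      na_threshold: float = NA_BIND_THRESHOLD) -> list[IonBinding]:
    """Assign ions to ionizable groups by the distance criteria.

    Candidate pairs within threshold are resolved greedily by increasing
    distance (ties by residue order in the structure), so each ion binds at
    most one group and each group binds at most one ion.  The result is
    independent of the order of the ion list.
    """
    blocks = {bid: structure.block(bid) for bid, _ in structure.ionizable_sites}
    order = {bid: i for i, (bid, _) in enumerate(structure.ionizable_sites)}
    candidates = []
    for idx, ion in enumerate(ions):
        for bid, group in structure.ionizable_sites:
            if ion.kind == "CL" and group in CL_BINDING_GROUPS:
                d = _min_distance(ion.coords, blocks[bid],
                                  lambda a: a.element == "H")
                thr = cl_threshold
            elif ion.kind == "NA" and group in NA_BINDING_GROUPS:
                d = _min_distance(ion.coords, blocks[bid],
                                  lambda a: a.element == "O"
                                  and a.name in _CARBOXYLATE_O)
                thr = na_threshold
            else:
                continue
            if d <= thr:
                candidates.append((d, order[bid], idx, bid, ion))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_ions: set[int] = set()
    used_blocks: set[str] = set()
    bindings = []
    for d, _, idx, bid, ion in candidates:
        if idx in used_ions or bid in used_blocks:
            continue
        used_ions.add(idx)
        used_blocks.add(bid)
        bindings.append(IonBinding(idx, ion, bid, d))
    bindings.sort(key=lambda b: order[b.residue_block_id])
    return bindings


def neutralize(charge_sites: list[ChargeSite],
               bindings: list[IonBinding]) -> list[ChargeSite]:
    """Flag residues with a bound ion as neutralized.

    Neutralized sites keep their charge value — they still act as field
    sources for the core-dipole correction — but are excluded from the
    charge-dipole sums.
    """
    bound_blocks = {b.residue_block_id for b in bindings}
    return [replace(cs, neutralized=cs.neutralized
                    or cs.block_id in bound_blocks)
            for cs in charge_sites]


# --- minimum-volume enclosing ellipsoid ------------------------------------

def _mvee(points: np.ndarray, tol: float = 1e-6,
          max_iter: int = 10000) -> tuple[np.ndarray, np.ndarray]:
    """Khachiyan's algorithm: (centre, A) with (x-c)^T A (x-c) <= 1."""
    n, d = points.shape
    q = np.column_stack([points, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x = q @ (u[:, None] * q.T)
        m = np.einsum("ij,ji->i", q.T @ np.linalg.inv(x), q)
        j = int(np.argmax(m))
        step = (m[j] - d - 1.0) / ((d + 1.0) * (m[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    c = u @ points
    cov = points.T @ (u[:, None] * points) - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    return c, a


def ellipsoid_cutoff(structure: ProteinStructure,
                     env_sites: list[EnvironmentSite],
                     cutoff: float) -> list[EnvironmentSite]:
    """Trim the water shell to an inflated enclosing ellipsoid; keep all ions.

    The minimum-volume ellipsoid enclosing all protein atoms is computed, its
    semi-axes are each grown by ``cutoff`` (angstrom), and waters outside the
    inflated surface are dropped.  Ions are kept unconditionally to preserve
    charge balance.  Degenerate (coplanar) proteins fall back to a sphere.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    pts = np.array([a.coords for a in structure.atoms])

    def keep_water(pos: np.ndarray) -> bool:
        return inside(pos)

    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-6) < 3:
        centre = pts.mean(axis=0)
        radius = np.linalg.norm(pts - centre, axis=1).max() + cutoff

        def inside(pos):
            return np.linalg.norm(pos - centre) <= radius
    else:
        centre, a = _mvee(pts)
        evals, evecs = np.linalg.eigh(a)
        semi = 1.0 / np.sqrt(evals) + cutoff
        a_inflated = evecs @ np.diag(1.0 / semi**2) @ evecs.T

        def inside(pos):
            d = pos - centre
            return float(d @ a_inflated @ d) <= 1.0

    return [s for s in env_sites
            if s.kind != "WATER" or keep_water(s.coords)]


# --- configuration combinatorics -------------------------------------------

def config_name(na_sites, cl_sites) -> str:
    """Six-character padded code, or "standard" / "ABCDXYZW" for the extremes."""
    na = sorted(na_sites, key=NA_LETTERS.index)
    cl = sorted(cl_sites, key=CL_LETTERS.index)
    if len(na) != len(cl):
        raise ValueError("ions come in pairs: |na_sites| must equal |cl_sites|")
    if not na:
        return "standard"
    if len(na) == 4:
        return "ABCDXYZW"
    return "".join(na).ljust(3, "-") + "".join(cl).ljust(3, "-")


def enumerate_configurations() -> list[IonConfiguration]:
    """All 70 pair-balanced ion placements, numbered 1..70.

    Number 1 is "standard" (no ions) and 70 is the fully loaded "ABCDXYZW";
    within each pair-count class the ordering is lexicographic in the site
    letters (Na letters A<B<C<D, Cl letters X<Y<Z<W).
    """
    configs = []
    number = 1
    for k in range(5):
        for na in itertools.combinations(NA_LETTERS, k):
            for cl in itertools.combinations(CL_LETTERS, k):
                configs.append(IonConfiguration(
                    frozenset(na), frozenset(cl),
                    config_name(na, cl), number))
                number += 1
    return configs
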