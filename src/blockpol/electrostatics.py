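"""Charge dipole moment, point-charge fields and the core-dipole correction.

Everything in this module works in Hartree atomic units: positions in bohr,
charges in e, dipoles in e.bohr, fields in Eh/(e.bohr).  There is no
4*pi*eps0 factor.

The molecular dipole decomposes exactly into a *charge* dipole — from the
arrangement of net ionic charges on the ionizable groups — and a *core*
dipole — the sum of per-block bonding dipoles, each corrected linearly by
the local electric field of all the charges.  Charges shift core dipoles but
never touch polarizability tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DipoleDecomposition",
    "PointCharge",
    "charge_dipole",
    "field_from_charges",
    "correct_core_dipoles",
]

#: Sources closer than this to an evaluation point are unphysical overlaps.
MIN_FIELD_DISTANCE = 0.1  # bohr


@dataclass(frozen=True)
class PointCharge:
    q: float               # e
    position: np.ndarray   # bohr


@dataclass(frozen=True)
class DipoleDecomposition:
    mu_charge: np.ndarray
    mu_core: np.ndarray

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu_charge + self.mu_core


def charge_dipole(charges: list[PointCharge],
                  neutrality_tol: float = 1e-2) -> np.ndarray:
    """Charge dipole moment (e.bohr) of a set of point charges.

    Computed as Q+ * R with R the vector from the centre of negative charge
    to the centre of positive charge; for a neutral set this equals
    sum(q_i r_i) and is origin independent.  A warning is emitted when the
    set is measurably non-neutral (the result then depends on the origin).
    """
    if not charges:
        return np.zeros(3)
    q = np.array([c.q for c in charges], dtype=float)
    r = np.array([c.position for c in charges], dtype=float)
    qpos = q[q > 0]
    qneg = q[q < 0]
    if qpos.size == 0 or qneg.size == 0:
        if abs(q.sum()) > neutrality_tol:
            warnings.warn("charge set is non-neutral; dipole is origin dependent",
                          stacklevel=2)
        return (q[:, None] * r).sum(axis=0)
    if abs(qpos.sum() + qneg.sum()) > neutrality_tol:
        warnings.warn(
            f"charge set is non-neutral (net {q.sum():+.3f} e); "
            f"dipole is origin dependent", stacklevel=2)
    centre_pos = (qpos[:, None] * r[q > 0]).sum(axis=0) / qpos.sum()
    centre_neg = (np.abs(qneg)[:, None] * r[q < 0]).sum(axis=0) / np.abs(qneg).sum()
    return qpos.sum() * (centre_pos - centre_neg)


def field_from_charges(point: np.ndarray,
                       charges: list[PointCharge]) -> np.ndarray:
    """Electric field (a.u.) at ``point`` from a set of point charges.

    F = sum q / |r|^2 * r_hat, with r_hat pointing from each charge towards
    the evaluation point (so a positive charge pushes field outward).
    """
    point = np.asarray(point, dtype=float)
    f = np.zeros(3)
    for c in charges:
        rvec = point - np.asarray(c.position, dtype=float)
        r = np.linalg.norm(rvec)
        if r < MIN_FIELD_DISTANCE:
            raise ValueError(
                f"field evaluation point within {MIN_FIELD_DISTANCE} bohr of a "
                f"charge (r = {r:.3g}); unphysical overlap")
        f += c.q * rvec / r**3
    return f


def correct_core_dipoles(mu0: np.ndarray, alphas: np.ndarray,
                         fields: np.ndarray) -> np.ndarray:
    """Field-corrected core dipoles, mu = mu0 + alpha.F per block.

    ``mu0``: (n, 3) permanent block dipoles; ``alphas``: (n, 3, 3) block
    tensors; ``fields``: (n, 3) local fields.  The tensors are inputs only —
    charges never modify polarizabilities.
    """
    mu0 = np.asarray(mu0, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    fields = np.asarray(fields, dtype=float)
    return mu0 + np.einsum("nij,nj->ni", alphas, fields)
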