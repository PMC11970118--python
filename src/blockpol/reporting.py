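"""Scalar summaries and comparison metrics for dipoles and polarizabilities."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PropertyReport",
    "isotropic",
    "anisotropy",
    "dipole_deviation",
]


def isotropic(alpha: np.ndarray) -> float:
    """Isotropic polarizability, alpha_iso = Tr(alpha)/3."""
    alpha = np.asarray(alpha, float)
    return float(np.trace(alpha)) / 3.0


def anisotropy(alpha: np.ndarray) -> float:
    """First polarizability-anisotropy invariant.

    Delta_alpha = sqrt(((a1-a2)^2 + (a2-a3)^2 + (a3-a1)^2)/2) over the
    eigenvalues; zero iff the tensor is isotropic, invariant under rotation.
    """
    e = np.linalg.eigvalsh(np.asarray(alpha, float))
    return float(np.sqrt(((e[0] - e[1]) ** 2 + (e[1] - e[2]) ** 2
                          + (e[2] - e[0]) ** 2) / 2.0))


def dipole_deviation(mu_a: np.ndarray, mu_b: np.ndarray) -> tuple[float, float]:
    """(percent magnitude deviation, angle in degrees) of mu_a vs mu_b.

    The magnitude deviation is relative to |mu_b| (the reference); the angle
    lies in [0, 180] degrees.
    """
    a = np.asarray(mu_a, float)
    bvec = np.asarray(mu_b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(bvec)
    if na == 0.0 or nb == 0.0:
        raise ValueError("dipole_deviation requires two nonzero vectors")
    pct = 100.0 * abs(na - nb) / nb
    cosang = np.clip(a @ bvec / (na * nb), -1.0, 1.0)
    return pct, float(np.degrees(np.arccos(cosang)))


@dataclass
class PropertyReport:
    """Full prediction output, everything in atomic units.

    ``alpha_eigenvalues`` are sorted ascending, so the third entry is the
    component that aligns with the long molecular axis for elongated
    systems.
    """

    mu_charge: np.ndarray
    mu_core: np.ndarray
    alpha_total: np.ndarray
    per_block: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu_charge + self.mu_core

    @property
    def alpha_iso(self) -> float:
        return isotropic(self.alpha_total)

    @property
    def alpha_aniso(self) -> float:
        return anisotropy(self.alpha_total)

    @property
    def alpha_eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.alpha_total)

    def to_dict(self) -> dict:
        e = self.alpha_eigenvalues
        return {
            "schema": "blockpol-report-1",
            "mu_charge": self.mu_charge.tolist(),
            "mu_core": self.mu_core.tolist(),
            "mu_total": self.mu_total.tolist(),
            "mu_total_abs": float(np.linalg.norm(self.mu_total)),
            "alpha_total": self.alpha_total.tolist(),
            "alpha_iso": self.alpha_iso,
            "alpha_aniso": self.alpha_aniso,
            "alpha_eigenvalues": e.tolist(),
            "per_block": self.per_block,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)
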