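"""Applequist dipole interaction model (ADIM) with Thole-style damping.

Point polarizable sites couple through the dipole field tensor
``T = (3 r r^T - r^2 I) / r^5``; each site's dipole responds to the external
field plus the field of every other site's dipole.  Solving the coupled
linear system gives the induced dipoles, and the relay matrix
``B = (A^-1 - T)^-1`` (A = block-diagonal of the site tensors) yields
environment-corrected site polarizabilities as row sums of its 3x3 blocks.

Sites sharing a ``molecule_id`` do not interact: interactions inside a
molecule are already contained in its database entries, so any change in
properties is attributable to the environment alone.

At short range the bare tensor diverges and the coupled system can become
non-physical (the polarization catastrophe), so the tensor is screened by a
Thole-type damping function of the reduced distance
``u = b * r / (alpha_iso_i * alpha_iso_j)^(1/6)``.  The default screening is
the third-order truncated-exponential factor

    S(u) = 1 - exp(-u) * (1 + u + u^2/2 + u^3/6),

which tends to 1 at large separation and suppresses the screened tensor to
zero as r -> 0 (S ~ u^4/24).  Alternative schemes ("drude_exp",
"thole_linear", "none") are selectable; see :data:`DAMPING_SCHEMES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_THOLE_B

__all__ = [
    "PolarizableSystem",
    "AdimResult",
    "DAMPING_SCHEMES",
    "field_tensor",
    "thole_screen",
    "damped_field_tensor",
    "solve_induced",
    "corrected_polarizabilities",
]


class PolarizationCatastropheError(np.linalg.LinAlgError):
    pass


def field_tensor(r_a: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    """Dipole-dipole field tensor (3 r r^T - r^2 I)/r^5 between two sites (bohr)."""
    rvec = np.asarray(r_a, float) - np.asarray(r_b, float)
    r = np.linalg.norm(rvec)
    if r < 1e-6:
        raise ValueError(f"sites coincide (r = {r:.2g} bohr)")
    return (3.0 * np.outer(rvec, rvec) - r * r * np.eye(3)) / r**5


def _screen_thole_exp(u: float) -> float:
    return 1.0 - np.exp(-u) * (1.0 + u + u * u / 2.0 + u**3 / 6.0)


def _screen_drude_exp(u: float) -> float:
    return 1.0 - (1.0 + 0.5 * u) * np.exp(-u)


#: name -> scalar screening S(u) multiplying the field tensor
#: ("thole_linear" is handled tensorially, "none" leaves T bare).
DAMPING_SCHEMES = {
    "thole_exp": _screen_thole_exp,
    "drude_exp": _screen_drude_exp,
    "thole_linear": None,
    "none": None,
}

DEFAULT_DAMPING = "thole_exp"


def thole_screen(u: float, scheme: str = DEFAULT_DAMPING) -> float:
    """Scalar screening factor S(u) for the multiplicative schemes."""
    fn = DAMPING_SCHEMES.get(scheme)
    if fn is None:
        raise ValueError(f"scheme {scheme!r} has no scalar screening factor")
    return fn(u)


def damped_field_tensor(r_a, r_b, alpha_iso_a: float, alpha_iso_b: float,
                        b: float = DEFAULT_THOLE_B,
                        scheme: str = DEFAULT_DAMPING) -> np.ndarray:
    """Screened dipole field tensor between two polarizable sites.

    If either site has zero isotropic polarizability no damping is applied
    (the site behaves as a bare point source).
    """
    if scheme not in DAMPING_SCHEMES:
        raise ValueError(f"unknown damping scheme {scheme!r}; "
                         f"choose from {sorted(DAMPING_SCHEMES)}")
    t = field_tensor(r_a, r_b)
    if scheme == "none" or alpha_iso_a <= 0.0 or alpha_iso_b <= 0.0:
        return t
    if b <= 0:
        raise ValueError("Thole b must be positive")
    rvec = np.asarray(r_a, float) - np.asarray(r_b, float)
    r = float(np.linalg.norm(rvec))
    u = b * r / (alpha_iso_a * alpha_iso_b) ** (1.0 / 6.0)
    if scheme == "thole_linear":
        if u >= 1.0:
            return t
        lam3 = 4.0 * u**3 - 3.0 * u**4
        lam5 = u**4
        return (3.0 * lam5 * np.outer(rvec, rvec)
                - lam3 * r * r * np.eye(3)) / r**5
    return DAMPING_SCHEMES[scheme](u) * t


@dataclass
class PolarizableSystem:
    """Collection of interaction sites entering the ADIM solve.

    Positions in bohr, tensors in bohr^3, dipoles in e.bohr.  Sites with the
    same ``molecule_id`` are mutually excluded; ``exclusions`` adds further
    site-index pairs.
    """

    site_ids: list
    positions: np.ndarray            # (n, 3) bohr
    alphas: np.ndarray               # (n, 3, 3)
    mu0: np.ndarray                  # (n, 3) permanent dipoles
    molecule_ids: list
    external_field: np.ndarray | None = None  # (n, 3)
    exclusions: set = field(default_factory=set)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        n = len(self.positions)
        self.alphas = np.asarray(self.alphas, float).reshape(n, 3, 3)
        self.mu0 = np.asarray(self.mu0, float).reshape(n, 3)
        if self.external_field is None:
            self.external_field = np.zeros((n, 3))
        self.external_field = np.asarray(self.external_field, float).reshape(n, 3)
        if len(self.site_ids) != n or len(self.molecule_ids) != n:
            raise ValueError("site_ids/molecule_ids length mismatch")
        for i, a in enumerate(self.alphas):
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError(f"site {self.site_ids[i]}: tensor not symmetric")
            if np.linalg.eigvalsh(a).min() < -1e-10:
                raise ValueError(f"site {self.site_ids[i]}: tensor not PSD")

    def __len__(self) -> int:
        return len(self.positions)

    def interacts(self, i: int, j: int) -> bool:
        if i == j:
            return False
        if self.molecule_ids[i] == self.molecule_ids[j]:
            return False
        return (i, j) not in self.exclusions and (j, i) not in self.exclusions

    def iso(self, i: int) -> float:
        return float(np.trace(self.alphas[i])) / 3.0


@dataclass
class AdimResult:
    site_ids: list
    induced_dipoles: np.ndarray      # (n, 3), response part only
    dipoles: np.ndarray              # (n, 3), permanent + induced
    corrected_alphas: np.ndarray     # (n, 3, 3)
    total_alpha: np.ndarray          # (3, 3)


def _coupling_matrix(system: PolarizableSystem, b: float,
                     damping: str) -> np.ndarray:
    """(3n, 3n) matrix of damped field tensors; zero for excluded pairs."""
    n = len(system)
    t = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not system.interacts(i, j):
                continue
            tij = damped_field_tensor(system.positions[i], system.positions[j],
                                      system.iso(i), system.iso(j), b, damping)
            t[3 * i:3 * i + 3, 3 * j:3 * j + 3] = tij
            t[3 * j:3 * j + 3, 3 * i:3 * i + 3] = tij
    return t


def solve_induced(system: PolarizableSystem, b: float = DEFAULT_THOLE_B,
                  damping: str = DEFAULT_DAMPING,
                  include_permanent_dipoles: bool = True) -> AdimResult:
    """Solve the mutual-induction equations by a direct dense solve.

    Each site's dipole is ``mu_i = mu0_i + alpha_i (F_ext,i + sum_j T_ij
    mu_j)``; with ``include_permanent_dipoles`` false the permanent dipoles
    do not radiate and only the external field drives the response.  The
    corrected polarizabilities from the relay matrix are included in the
    returned result.
    """
    n = len(system)
    t = _coupling_matrix(system, b, damping)
    a_blocks = np.zeros((3 * n, 3 * n))
    for i in range(n):
        a_blocks[3 * i:3 * i + 3, 3 * i:3 * i + 3] = system.alphas[i]
    f_ext = system.external_field.reshape(-1)
    mu0 = system.mu0.reshape(-1)
    lhs = np.eye(3 * n) - a_blocks @ t
    if include_permanent_dipoles:
        rhs = mu0 + a_blocks @ f_ext
    else:
        rhs = a_blocks @ f_ext
    try:
        mu = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise PolarizationCatastropheError(
            "singular ADIM system (polarization catastrophe); increase the "
            "Thole b coefficient or check for overlapping sites") from exc
    # residual of the fixed-point equation
    resid = np.linalg.norm(lhs @ mu - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if resid / scale > 1e-10:
        raise PolarizationCatastropheError(
            f"ADIM solve did not reach residual tolerance ({resid / scale:.2e})")
    if include_permanent_dipoles:
        full = mu.reshape(n, 3)
        induced = full - system.mu0
    else:
        induced = mu.reshape(n, 3)
        full = system.mu0 + induced
    per_site, total = corrected_polarizabilities(system, b, damping,
                                                 _coupling=t)
    return AdimResult(list(system.site_ids), induced, full, per_site, total)


def corrected_polarizabilities(system: PolarizableSystem,
                               b: float = DEFAULT_THOLE_B,
                               damping: str = DEFAULT_DAMPING,
                               _coupling: np.ndarray | None = None,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Environment-corrected per-site tensors from the relay matrix.

    ``B = (A^-1 - T)^-1`` is formed over the sites with invertible tensors;
    the corrected polarizability of site i is the row sum ``sum_j B_ij`` of
    3x3 blocks, and the total is the sum over all blocks of B.  Sites with a
    singular (zero) tensor are excluded from the relay and returned with
    zero correction.
    """
    n = len(system)
    active = [i for i in range(n) if np.abs(np.trace(system.alphas[i])) > 1e-12]
    idx = {site: k for k, site in enumerate(active)}
    m = len(active)
    per_site = np.array([system.alphas[i].copy() for i in range(n)]) \
        if n else np.zeros((0, 3, 3))
    if m:
        t = _coupling if _coupling is not None \
            else _coupling_matrix(system, b, damping)
        ainv_t = np.zeros((3 * m, 3 * m))
        for i in active:
            k = idx[i]
            ainv_t[3 * k:3 * k + 3, 3 * k:3 * k + 3] = \
                np.linalg.inv(system.alphas[i])
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                tij = t[3 * i:3 * i + 3, 3 * j:3 * j + 3]
                ainv_t[3 * ii:3 * ii + 3, 3 * jj:3 * jj + 3] = -tij
                ainv_t[3 * jj:3 * jj + 3, 3 * ii:3 * ii + 3] = -tij
        try:
            relay = np.linalg.inv(ainv_t)
        except np.linalg.LinAlgError as exc:
            raise PolarizationCatastropheError(
                "singular relay matrix (polarization catastrophe); increase "
                "the Thole b coefficient or check for overlapping sites") from exc
        for i in active:
            k = idx[i]
            rows = relay[3 * k:3 * k + 3, :]
            per_site[i] = rows.reshape(3, m, 3).sum(axis=1)
    total = per_site.sum(axis=0) if n else np.zeros((3, 3))
    asym = np.linalg.norm(total - total.T)
    if asym > 1e-8 * max(1.0, np.linalg.norm(total)):
        raise PolarizationCatastropheError(
            f"total polarizability asymmetric (|asym| = {asym:.2e})")
    total = 0.5 * (total + total.T)
    return per_site, total
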