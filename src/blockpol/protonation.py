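"""Henderson-Hasselbalch charge assignment and isoelectric-point solver.

At a given pH every ionizable group carries the fractional charge of its
ionized population: ``q = -1/(1 + 10^(pKa - pH))`` for acids and
``q = +1/(1 + 10^(pH - pKa))`` for bases.  Side-chain charges are applied
directly at the block charge centre.

The terminal groups use a compensation convention: the database's entries
were created for the zwitterionic peptide, i.e. with -NH3+ (+1) and -COO-
(-1) already built in.  The charge actually *applied* to a terminal block is
therefore the difference between its Henderson-Hasselbalch effective charge
and the built-in zwitterion charge — an N-terminus that should carry +0.6
gets a compensating -0.4.  Net charge and the isoelectric point are always
computed with the true chemical charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .structure_model import ProteinStructure

__all__ = [
    "PkaTable",
    "ChargeSite",
    "DEFAULT_PKA",
    "henderson_charge",
    "terminal_compensation",
    "assign_charges",
    "net_charge",
    "isoelectric_point",
]

ACIDIC = "acidic"
BASIC = "basic"


@dataclass(frozen=True)
class PkaTable:
    """pKa values and chemical sign per ionizable group."""

    groups: dict = field(default_factory=lambda: dict(_DEFAULT_GROUPS))

    def sign(self, group: str) -> str:
        return self._get(group)[0]

    def pka(self, group: str) -> float:
        return self._get(group)[1]

    def _get(self, group: str):
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"unknown ionizable group {group!r}")


# True chemical classification; the pKa values are the package defaults.
_DEFAULT_GROUPS = {
    "GLU": (ACIDIC, 4.4),
    "ASP": (ACIDIC, 4.4),
    "CYS": (ACIDIC, 8.5),
    "TYR": (ACIDIC, 10.1),
    "ARG": (BASIC, 12.5),
    "LYS": (BASIC, 10.6),
    "HIS": (BASIC, 6.6),
    "CTER": (ACIDIC, 4.0),
    "NTER": (BASIC, 8.0),
}

DEFAULT_PKA = PkaTable()

#: Zwitterion reference charge already built into the database entries.
_ZWITTERION_CHARGE = {"NTER": +1.0, "CTER": -1.0}


@dataclass
class ChargeSite:
    block_id: str
    group: str
    position: np.ndarray  # angstrom (block charge centre)
    q: float              # e, the charge actually applied
    neutralized: bool = False


def henderson_charge(group: str, pka: float, ph: float,
                     sign: str | None = None) -> float:
    """Fractional charge of an ionizable group at the given pH.

    ``group`` selects the acidic or basic branch via the default table's
    chemical sign (pass "ASP"..."NTER"), unless ``sign`` overrides it.
    The result lies in (-1, 0) for acids and (0, 1) for bases.
    """
    if not (np.isfinite(pka) and np.isfinite(ph)):
        raise ValueError("pKa and pH must be finite")
    if sign is None:
        sign = DEFAULT_PKA.sign(group)
    if sign == ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def terminal_compensation(group: str, q_effective: float) -> float:
    """Charge applied to a terminal block given its effective chemical charge.

    ``q_applied = q_effective - q_zwitterion`` with the zwitterion reference
    +1 for NTER and -1 for CTER.
    """
    if group not in _ZWITTERION_CHARGE:
        raise ValueError(f"{group!r} is not a terminal group")
    return q_effective - _ZWITTERION_CHARGE[group]


def assign_charges(structure: ProteinStructure,
                   pka_table: PkaTable = DEFAULT_PKA,
                   ph: float = 7.3,
                   mode: str = "charged") -> list[ChargeSite]:
    """One ChargeSite per ionizable group of the structure.

    In "standard" mode (the zwitterion baseline used when no ions are
    present) no charges are placed at all and the list is empty.
    """
    if mode == "standard":
        return []
    if mode != "charged":
        raise ValueError(f"unknown mode {mode!r}")
    sites = []
    for block_id, group in structure.ionizable_sites:
        q = henderson_charge(group, pka_table.pka(group), ph,
                             sign=pka_table.sign(group))
        if group in _ZWITTERION_CHARGE:
            q = terminal_compensation(group, q)
        block = structure.block(block_id)
        sites.append(ChargeSite(block_id, group, block.charge_centre.copy(), q))
    return sites


def net_charge(ph: float, composition, pka_table: PkaTable = DEFAULT_PKA) -> float:
    """Total chemical charge (e) of a multiset of ionizable groups at a pH."""
    return sum(henderson_charge(g, pka_table.pka(g), ph, sign=pka_table.sign(g))
               for g in composition)


def isoelectric_point(composition, pka_table: PkaTable = DEFAULT_PKA) -> float:
    """pH in [0, 14] at which the net charge vanishes.

    The net charge is strictly decreasing in pH, so the root is unique; it is
    bracketed on [0, 14] and solved to |net| < 1e-9.
    """
    groups = list(composition)
    signs = {pka_table.sign(g) for g in groups}
    if signs != {ACIDIC, BASIC}:
        raise ValueError("composition needs at least one acidic and one basic group")
    f = lambda ph: net_charge(ph, groups, pka_table)
    if f(0.0) <= 0.0 or f(14.0) >= 0.0:
        raise ValueError("net charge does not change sign on pH in [0, 14]")
    return float(brentq(f, 0.0, 14.0, xtol=1e-12, rtol=8.9e-16))
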