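"""End-to-end prediction: structure -> blocks -> charges -> ions -> ADIM.

The stages run once, in a fixed order:

1. read the protonated structure and decompose it into building blocks;
   place database dipoles/tensors into the global frame;
2. assign Henderson-Hasselbalch charges at the configured pH, detect bound
   ions and neutralize their residues; compute the charge dipole from the
   non-neutralized sites;
3. correct every block's core dipole with the field of all charges
   (neutralized residues and ions included as field sources);
4. trim the water shell to the inflated enclosing ellipsoid (ions are all
   kept) and solve the Thole-damped Applequist model over protein blocks
   plus environment sites, with intra-molecular exclusions;
5. aggregate: mu_total = mu_charge + sum of corrected core dipoles; the
   molecular polarizability is the relay row-sum total over the protein
   blocks and any bound ions.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__ as _version
from .adim import DEFAULT_DAMPING, PolarizableSystem, solve_induced
from .block_database import BlockDB, place_entry
from .constants import (
    BOHR_PER_ANGSTROM,
    CL_BIND_THRESHOLD,
    CL_POLARIZABILITY,
    DEFAULT_CUTOFF,
    DEFAULT_THOLE_B,
    NA_BIND_THRESHOLD,
    NA_POLARIZABILITY,
    WATER_POLARIZABILITY,
)
from .electrostatics import (
    PointCharge,
    charge_dipole,
    correct_core_dipoles,
    field_from_charges,
)
from .ion_environment import (
    detect_bound_ions,
    ellipsoid_cutoff,
    enumerate_configurations,
    neutralize,
)
from .protonation import DEFAULT_PKA, PkaTable, assign_charges
from .reporting import PropertyReport, isotropic
from .structure_model import EnvironmentSite, ProteinStructure, read_structure

__all__ = ["RunConfig", "run_prediction", "sweep_configurations"]

logger = logging.getLogger("blockpol")

_AB = BOHR_PER_ANGSTROM


@dataclass(frozen=True)
class RunConfig:
    """Run parameters (distances in angstrom, polarizabilities in bohr^3)."""

    ph: float = 7.3
    mode: str = "charged"            # "charged" or "standard" (zwitterion)
    thole_b: float = DEFAULT_THOLE_B
    cutoff: float = DEFAULT_CUTOFF
    cl_threshold: float = CL_BIND_THRESHOLD
    na_threshold: float = NA_BIND_THRESHOLD
    damping: str = DEFAULT_DAMPING
    include_permanent_dipoles: bool = True
    far_ion_fields: bool = True      # non-bound ions as core-field sources
    na_alpha: float = NA_POLARIZABILITY
    cl_alpha: float = CL_POLARIZABILITY
    water_alpha: float = WATER_POLARIZABILITY
    pka_table: PkaTable = DEFAULT_PKA
    seed: int = 0

    def __post_init__(self):
        for name in ("thole_b", "cutoff", "cl_threshold", "na_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def run_prediction(pdb_text: str, db: BlockDB,
                   config: RunConfig = RunConfig()) -> PropertyReport:
    """Predict dipole moment and polarizability from protonated PDB text."""
    structure, env = read_structure(pdb_text)
    return predict_from_structure(structure, env, db, config)


def predict_from_structure(structure: ProteinStructure,
                           env: list[EnvironmentSite],
                           db: BlockDB,
                           config: RunConfig = RunConfig()) -> PropertyReport:
    # stage 1: database placement
    placed = [(b, *place_entry(db[b.db_key], b)) for b in structure.blocks]
    centres = np.array([b.charge_centre for b, _, _ in placed]) * _AB
    logger.info("stage 1: %d blocks placed from database", len(placed))

    # stage 2: charges and ion detection
    ions = [s for s in env if s.kind in ("NA", "CL")]
    waters = [s for s in env if s.kind == "WATER"]
    charge_sites = assign_charges(structure, config.pka_table,
                                  config.ph, config.mode)
    bindings = detect_bound_ions(structure, ions,
                                 config.cl_threshold, config.na_threshold)
    charge_sites = neutralize(charge_sites, bindings)
    active = [cs for cs in charge_sites if not cs.neutralized]
    mu_charge = charge_dipole(
        [PointCharge(cs.q, cs.position * _AB) for cs in active])
    logger.info("stage 2: pH %.2f mode=%s: %d charge sites, %d bound ions, "
                "|mu_charge| = %.3f a.u.", config.ph, config.mode,
                len(charge_sites), len(bindings), np.linalg.norm(mu_charge))

    # stage 3: core-dipole field correction
    bound_ion_idx = {b.ion_index for b in bindings}
    sources = {cs.block_id: PointCharge(cs.q, cs.position * _AB)
               for cs in charge_sites}
    ion_sources = [PointCharge(ion.charge, ion.coords * _AB)
                   for i, ion in enumerate(ions)
                   if i in bound_ion_idx or config.far_ion_fields]
    fields = np.zeros((len(placed), 3))
    for k, (block, _, _) in enumerate(placed):
        charges = [pc for bid, pc in sources.items() if bid != block.block_id]
        charges += ion_sources
        if charges:
            fields[k] = field_from_charges(centres[k], charges)
    mu_core0 = correct_core_dipoles(
        np.array([mu for _, mu, _ in placed]),
        np.array([alpha for _, _, alpha in placed]), fields)
    logger.info("stage 3: core dipoles corrected with %d field sources",
                len(sources) + len(ion_sources))

    # stage 4: environment trimming + ADIM
    kept_waters = [s for s in ellipsoid_cutoff(structure, waters, config.cutoff)]
    site_ids = [b.block_id for b, _, _ in placed]
    positions = [c for c in centres]
    alphas = [alpha for _, _, alpha in placed]
    mu0s = [m for m in mu_core0]
    molecule_ids = [f"chain:{b.block_id.split(':', 1)[0]}" for b, _, _ in placed]
    env_alpha = {"NA": config.na_alpha, "CL": config.cl_alpha,
                 "WATER": config.water_alpha}
    adim_index: dict[str, int] = {}
    for i, ion in enumerate(ions):
        adim_index[f"ion:{i}"] = len(site_ids)
        site_ids.append(f"ion:{i}")
        positions.append(ion.coords * _AB)
        alphas.append(env_alpha[ion.kind] * np.eye(3))
        mu0s.append(np.zeros(3))
        molecule_ids.append(f"ion:{i}")
    for i, w in enumerate(kept_waters):
        site_ids.append(f"water:{i}")
        positions.append(w.coords * _AB)
        alphas.append(env_alpha["WATER"] * np.eye(3))
        mu0s.append(np.zeros(3))
        molecule_ids.append(f"water:{i}")
    system = PolarizableSystem(site_ids, np.array(positions), np.array(alphas),
                               np.array(mu0s), molecule_ids)
    result = solve_induced(system, config.thole_b, config.damping,
                           config.include_permanent_dipoles)
    logger.info("stage 4: ADIM over %d sites (%d blocks, %d ions, %d waters)",
                len(site_ids), len(placed), len(ions), len(kept_waters))

    # stage 5: aggregation over the molecule (protein blocks + bound ions)
    mol_idx = list(range(len(placed)))
    mol_idx += [adim_index[f"ion:{i}"] for i in sorted(bound_ion_idx)]
    mu_core = result.dipoles[mol_idx].sum(axis=0)
    alpha_total = result.corrected_alphas[mol_idx].sum(axis=0)
    alpha_total = 0.5 * (alpha_total + alpha_total.T)

    per_block = []
    for k, (block, mu0, alpha) in enumerate(placed):
        per_block.append({
            "block_id": block.block_id,
            "db_key": block.db_key,
            "mu0": mu0.tolist(),
            "mu_corrected": result.dipoles[k].tolist(),
            "alpha_iso": isotropic(result.corrected_alphas[k]),
        })
    provenance = {
        "config": _config_dict(config),
        "version": _version,
        "n_blocks": len(placed),
        "n_ions": len(ions),
        "n_bound_ions": len(bindings),
        "n_waters_kept": len(kept_waters),
        "bound": [{"ion": f"ion:{b.ion_index}", "block": b.residue_block_id,
                   "distance_A": b.distance} for b in bindings],
    }
    return PropertyReport(mu_charge, mu_core, alpha_total, per_block, provenance)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["pka_table"] = {g: list(v) for g, v in config.pka_table.groups.items()}
    return d


def _anchor_letters(structure: ProteinStructure) -> tuple[dict, dict]:
    """Map site letters A-D (Na+/acidic) and X-W (Cl-/basic) to block ids.

    Letters run over the acidic side chains (ASP/GLU) in sequence order with
    CTER last, and the basic side chains (LYS/ARG) in sequence order with
    NTER last.
    """
    acidic = [bid for bid, g in structure.ionizable_sites if g in ("ASP", "GLU")]
    acidic += [bid for bid, g in structure.ionizable_sites if g == "CTER"]
    basic = [bid for bid, g in structure.ionizable_sites if g in ("LYS", "ARG")]
    basic += [bid for bid, g in structure.ionizable_sites if g == "NTER"]
    if len(acidic) != 4 or len(basic) != 4:
        raise ValueError(
            f"configuration sweep needs exactly 4 acidic and 4 basic anchor "
            f"groups, found {len(acidic)} acidic / {len(basic)} basic")
    return (dict(zip("ABCD", acidic)), dict(zip("XYZW", basic)))


def _assign_ions_to_letters(structure: ProteinStructure,
                            ions: list[EnvironmentSite]) -> dict[str, int]:
    """Greedy nearest-assignment of placed ions to the eight letter sites."""
    na_map, cl_map = _anchor_letters(structure)
    assignment: dict[str, int] = {}
    for letter_map, kind in ((na_map, "NA"), (cl_map, "CL")):
        cand = []
        for letter, bid in letter_map.items():
            block = structure.block(bid)
            for i, ion in enumerate(ions):
                if ion.kind != kind:
                    continue
                d = min(np.linalg.norm(a.coords - ion.coords)
                        for a in block.atoms)
                cand.append((d, letter, i))
        cand.sort()
        used: set[int] = set()
        for d, letter, i in cand:
            if letter in assignment or i in used:
                continue
            assignment[letter] = i
            used.add(i)
        missing = set(letter_map) - set(assignment)
        if missing:
            raise ValueError(f"no {kind} ion available for sites {sorted(missing)}")
    return assignment


def sweep_configurations(pdb_text: str, db: BlockDB,
                         config: RunConfig = RunConfig(),
                         ) -> tuple[list[PropertyReport], pd.DataFrame]:
    """Run all 70 NaCl placement configurations of an 8-ion input.

    The input structure must provide one Na+ for each acidic letter site
    (A-D) and one Cl- for each basic site (X-W); each configuration keeps
    only its subset of ions (waters are always kept) and re-runs the full
    prediction.  Returns the per-configuration reports and a tidy summary
    table.
    """
    structure, env = read_structure(pdb_text)
    ions = [s for s in env if s.kind in ("NA", "CL")]
    waters = [s for s in env if s.kind == "WATER"]
    assignment = _assign_ions_to_letters(structure, ions)

    reports = []
    rows = []
    for cfg in enumerate_configurations():
        chosen = sorted(assignment[letter]
                        for letter in cfg.na_sites | cfg.cl_sites)
        sub_env = [ions[i] for i in chosen] + waters
        report = predict_from_structure(structure, sub_env, db, config)
        report.provenance["configuration"] = {
            "name": cfg.name, "number": cfg.number, "n_pairs": cfg.n_pairs}
        reports.append(report)
        mu = report.mu_total
        e = report.alpha_eigenvalues
        rows.append({
            "number": cfg.number, "name": cfg.name, "n_pairs": cfg.n_pairs,
            "mu_x": mu[0], "mu_y": mu[1], "mu_z": mu[2],
            "mu_abs": float(np.linalg.norm(mu)),
            "alpha_iso": report.alpha_iso,
            "alpha_aniso": report.alpha_aniso,
            "a11": e[0], "a22": e[1], "a33": e[2],
        })
    return reports, pd.DataFrame(rows)
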