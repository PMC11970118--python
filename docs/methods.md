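# Methods

This note records the model as implemented, the defaults and why they were
chosen, and what the synthetic data can and cannot validate.

## Property reconstruction from building blocks

A protein is partitioned exhaustively into building blocks: per residue one
backbone unit (N, H, Cα, Hα, C, O) and one side-chain unit (GLY has none),
plus one NTER (–NH₃⁺: N, H1–H3) and one CTER (–COO⁻: C, O, OXT) block per
chain.  The partition is exact — every atom belongs to exactly one block —
and deterministic.  This backbone/side-chain granularity is a documented
stand-in for finer quantum-topological fragmentations; the database key
schema (`RES:kind`) is deliberately open so finer schemes can be slotted in.

Each database entry stores a permanent dipole (e·bohr) and a symmetric PSD
polarizability tensor (bohr³) in a local frame anchored on three named atoms
of the block.  Placement builds the rotation by Gram–Schmidt (axis 1 along
atom1→atom2, axis 2 the in-plane component of atom1→atom3) and applies
μ = Rμ₀, α = Rα₀Rᵀ, preserving eigenvalues exactly.  Backbone blocks at the
chain ends lack some frame atoms (no N in the first backbone unit, no C/O in
the last), so the database carries three backbone variants per residue with
adapted frames.

Coordinates stay in ångström at the I/O boundary; all physics runs in
Hartree atomic units (1 Å = 1.8897259886 bohr).

## Protonation and charges

Fractional charges follow the two-branch Henderson–Hasselbalch form with the
default pKa table GLU/ASP 4.4, CYS 8.5, TYR 10.1, ARG 12.5, LYS 10.6,
HIS 6.6, CTER 4.0, NTER 8.0.  Charges sit at the block's
atomic-number-weighted centroid.

Terminals are special because the database entries describe the zwitterion:
the applied charge is the difference between the effective chemical charge
and the built-in ±1 reference.  Algebraically, applying the *acidic* formula
at the NTER pKa (and the basic one at the CTER pKa) yields the compensating
charge directly — that identity is why the pKa table can list the terminals
with inverted signs for bookkeeping.  Net charge and the isoelectric point
always use true chemical signs; since the net charge is strictly decreasing
in pH the root on [0, 14] is unique (solved with Brent's method to 1e-12;
for glucagon's composition it lands at pH 7.30).

In `standard` mode (the zwitterion baseline used when no ions are present)
no charges are placed at all, so the prediction is the plain sum of database
entries.

Limitations: single-site titration only (no coupled sites, no
structure-based pKa shifts), and hydrogens must already be present — the
package never adds them.

## Ions

Binding criteria: Cl⁻ ≤ 2.5 Å from any hydrogen of a basic group (LYS, ARG
side chains, NTER); Na⁺ ≤ 3.5 Å from any carboxylate oxygen of ASP/GLU side
chains or the CTER group.  Conflicts are resolved greedily by smallest
distance with ties broken by residue order, so each ion binds at most one
group and vice versa, and the result is independent of input ordering.
GLU shares the ASP threshold; all hydrogens of the group (not just the
formally charged ones) are eligible, the two conventions being the natural
reading of the distance criteria.

A bound ion neutralizes its group for the charge-dipole sum only.  The
group's charge and the ion's ±1 both remain Coulomb field sources for the
core-dipole correction, and by default *all* ions (bound or free) act as
field sources (`far_ion_fields=True`) — free ions exert weaker but nonzero
fields.  Because free ions are also polarizable ADIM sites, the flag allows
switching the static-field contribution off for sensitivity analysis.

Water trimming uses the minimum-volume enclosing ellipsoid of the protein
atoms (Khachiyan's algorithm, tolerance 1e-6), each semi-axis grown by the
cutoff (default 8 Å); waters outside are dropped, ions are kept
unconditionally to preserve charge balance.  Coplanar degenerate inputs
fall back to a bounding sphere.

Pair-balanced placements over the four acidic letters A–D and four basic
letters X, Y, Z, W give 1+16+36+16+1 = 70 configurations.  Letters map to
residues in sequence order with the terminus last in each class, and Cl
letters order as X<Y<Z<W (so {A,C}+{Z,W} names as `AC-ZW-`).  Within each
pair-count class numbering is lexicographic (1 = `standard`, 2–17 one pair,
18–53 two, 54–69 three, 70 = `ABCDXYZW`); the intra-class order is a
package convention.

## ADIM and Thole damping

The mutual-induction equations are solved densely: (I − **A T**)μ = μ⁰ +
**A F**_ext, with **A** the block-diagonal of site tensors and **T** the
damped dipole field tensors, zero for same-molecule pairs and self terms.
Dense direct solves are appropriate at the target scale (at most a few
thousand sites); the fixed-point residual is checked to 1e-10 relative.
Permanent block dipoles radiate by default (`include_permanent_dipoles`);
corrected polarizabilities come from row sums of the relay matrix
(**A**⁻¹ − **T**)⁻¹, built over the invertible sites (a zero-tensor site is
excluded from the relay and returned unchanged).  The total is checked for
symmetry (‖asym‖ < 1e-8) before symmetrization.

Damping: the reduced distance is u = b·r/(α_iso,Ω α_iso,Λ)^(1/6) with
b = 2.6, the value established in Drude polarizable force fields.  The
default screening multiplies **T** by the third-order truncated-exponential
factor

    S(u) = 1 − e^(−u) (1 + u + u²/2 + u³/6),

chosen because it has the two limits the model needs: S → 1 at large
separation (undamped to 1e-10 beyond u ≈ 40) and S·T → 0 at contact
(S ~ u⁴/24, so the screened tensor vanishes like r — no polarization
catastrophe).  The lower-order exponential screen 1 − (1+u/2)e^(−u), common
for screened *charge–charge* Drude interactions, is available as
`drude_exp` but diverges like 1/r² when used multiplicatively on the dipole
tensor; `thole_linear` (λ₃ = 4v³−3v⁴, λ₅ = v⁴) and `none` complete the
strategy set.  Sites with zero isotropic polarizability are treated as bare
point sources (no damping).

Aggregation: the molecular dipole and polarizability sum over the protein
blocks *plus bound ions* — a bound Cl⁻ contributes its ≈30 bohr³, a bound
Na⁺ a negligible 0.3 bohr³.  Free ions and waters polarize and are
polarized (that is the ≈2%-level environment effect) but are not counted in
the molecular totals; summing an arbitrary-size water shell into the
molecular tensor would make the result depend on the shell size rather than
on the molecule.

## Environment-site defaults

Na⁺ 0.3 bohr³ and Cl⁻ 30 bohr³ isotropic (the values appropriate for bound
alkali/halide ions in this model); water 9.8 bohr³ at a single site on the
oxygen, permanent dipole zero by default — the database treats whole
molecules as blocks, and a one-site isotropic water is the minimal
polarizable representation.  All three are overridable in `RunConfig`.

## Synthetic database and fixtures

The synthetic database emulates the *shape* of fitted block properties
without pretending to be fitted data: tensors are random SPD with isotropic
average `base_iso` × (heavy-atom count) and relative eigenvalue spread
`anisotropy_frac`, dipoles point along the first local frame axis with
magnitudes U(0.5, 2.0) e·bohr.  Defaults `base_iso = 10 bohr³` per heavy
atom and `anisotropy_frac = 0.3` put a 20–30-residue peptide in the low
thousands of bohr³ with anisotropies of tens to ~100 bohr³, the realistic
order of magnitude for small helical peptides.  Everything is a pure
function of the seed, stored as JSON with 12 significant digits so
save/load round-trips are bit-stable.

Fixtures are ideal α-helices (rise 1.5 Å, twist 100°/residue) with
schematic side chains: atoms walk outward from Cα with deterministic
offsets.  This geometry supports exactly what the package consumes —
block decomposition, charge centres, non-collinear local frames and
controlled ion-coordination distances (ions are placed at exact distances
from the outermost anchor atom of a group, pushed away from Cα so the
anchor stays the nearest atom).  It is not chemically accurate geometry,
and no fixture-based test should be read as validating bond lengths or
conformational realism.

The `saltbox` fixture's default sequence places its basic groups (LYS, ARG,
LYS plus NTER) near the N-terminal end and its acidic groups (ASP, GLU, ASP
plus CTER) near the C-terminal end.  The spatial charge separation gives a
large charge dipole (≈110 e·bohr for the 20-residue default), which
successive bound NaCl pairs then shrink — the geometry needed to exhibit
the salting-out dipole decrease.  An interleaved arrangement (e.g. a
glucagon-sequence helix, available via `sequence=GLUCAGON_SEQUENCE`) has a
nearly self-cancelling charge dipole, and removing pairs can then move |μ|
either way; the monotone trend is a property of charge-separated systems,
not of arbitrary sequences.

What passing tests show: unit and sign conventions, exact combinatorics,
the linear-response algebra (verified against closed forms and explicit
3N×3N inversions to 1e-10), conservation/invariance properties, and the
qualitative physics (dipole decrease with bound pairs, ≈30 bohr³ per bound
Cl⁻).  What they cannot show: quantitative agreement with ab initio
reference values for real proteins, which requires a fitted block database
and real geometries.

## Numerical choices

- Charge-dipole neutrality: deviations beyond 0.01 e trigger a warning
  (the dipole then depends on the origin); a fully neutralized set returns
  the zero vector.
- Field evaluation: at block charge centres, excluding the block's own
  charge; sources closer than 0.1 bohr raise (unphysical overlap).
- Field tensors: pairs closer than 1e-6 bohr raise; singular ADIM/relay
  systems raise a polarization-catastrophe error advising a larger b.
- MVEE: Khachiyan tolerance 1e-6, max 10 000 iterations.
- Altloc: highest-occupancy conformer per atom name; insertion codes kept.
- Problem sizes: the shipped workflows run 70-configuration sweeps on
  ~20-residue fixtures (~50 interaction sites per solve), a scale chosen to
  exercise every code path with sub-minute turnaround; the dense solver
  itself handles thousands of sites.
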