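import numpy as np
import pytest

import blockpol as bp
from blockpol.ion_environment import NA_LETTERS, CL_LETTERS
from blockpol.structure_model import EnvironmentSite


def _ion(kind, xyz):
    iso = 0.3 if kind == "NA" else 30.0
    q = 1.0 if kind == "NA" else -1.0
    return EnvironmentSite(kind, np.array(xyz, float), iso * np.eye(3), q)


@pytest.fixture(scope="module")
def lys_structure():
    pdb = bp.make_fixture("helix", 6, sequence=("ALA", "LYS", "SER", "ALA",
                                                "ASP", "LEU"))
    structure, _ = bp.read_structure(pdb)
    return structure


def _anchor(structure, resseq, atom_name):
    block = [b for b in structure.blocks
             if b.residue_id[1] == resseq and b.kind == "sidechain"][0]
    ca = [b for b in structure.blocks
          if b.residue_id[1] == resseq and b.kind == "backbone"][0].atom("CA")
    h = block.atom(atom_name)
    direction = (h.coords - ca.coords) / np.linalg.norm(h.coords - ca.coords)
    return h.coords, direction


class TestDetectBoundIons:
    def test_cl_within_threshold_binds(self, lys_structure):
        h, d = _anchor(lys_structure, 2, "HZ3")
        bindings = bp.detect_bound_ions(lys_structure, [_ion("CL", h + 2.4 * d)])
        assert len(bindings) == 1
        assert bindings[0].distance == pytest.approx(2.4, abs=1e-9)
        assert "sidechain" in bindings[0].residue_block_id

    def test_cl_beyond_threshold_does_not_bind(self, lys_structure):
        h, d = _anchor(lys_structure, 2, "HZ3")
        assert bp.detect_bound_ions(lys_structure, [_ion("CL", h + 2.6 * d)]) == []

    def test_na_binds_nearest_of_two_candidates(self, lys_structure):
        # Na+ 3.40 A from the ASP carboxylate and 3.45 A from another ASP-like
        # site: greedy nearest-assignment binds the closer residue only.
        o, d = _anchor(lys_structure, 5, "OD2")
        bindings = bp.detect_bound_ions(lys_structure, [_ion("NA", o + 3.4 * d)])
        assert len(bindings) == 1
        block = lys_structure.block(bindings[0].residue_block_id)
        assert block.residue_name == "ASP"

    def test_each_ion_and_each_residue_bind_at_most_once(self, lys_structure):
        h, d = _anchor(lys_structure, 2, "HZ3")
        ions = [_ion("CL", h + 2.0 * d), _ion("CL", h + 2.3 * d)]
        bindings = bp.detect_bound_ions(lys_structure, ions)
        assert len(bindings) == 1  # one LYS, so the second Cl stays free
        assert bindings[0].distance == pytest.approx(2.0, abs=1e-9)

    def test_order_independence(self, saltbox_pdb):
        structure, env = bp.read_structure(saltbox_pdb)
        ions = [s for s in env if s.kind in ("NA", "CL")]
        ref = {(b.residue_block_id, round(b.distance, 9))
               for b in bp.detect_bound_ions(structure, ions)}
        perm = {(b.residue_block_id, round(b.distance, 9))
                for b in bp.detect_bound_ions(structure, ions[::-1])}
        assert ref == perm and len(ref) == 8


class TestNeutralize:
    def test_no_bindings_is_identity(self, lys_structure):
        sites = bp.assign_charges(lys_structure, ph=7.3)
        out = bp.neutralize(sites, [])
        assert [s.q for s in out] == [s.q for s in sites]
        assert not any(s.neutralized for s in out)

    def test_bound_residue_flagged_but_charge_kept(self, lys_structure):
        h, d = _anchor(lys_structure, 2, "HZ3")
        bindings = bp.detect_bound_ions(lys_structure, [_ion("CL", h + 2.4 * d)])
        sites = bp.neutralize(bp.assign_charges(lys_structure, ph=7.3), bindings)
        lys = [s for s in sites if s.group == "LYS"][0]
        assert lys.neutralized and lys.q == pytest.approx(0.99950, abs=1e-4)

    def test_all_bound_gives_zero_charge_dipole(self, lys_structure):
        sites = bp.assign_charges(lys_structure, ph=7.3)
        neutralized = [bp.ChargeSite(s.block_id, s.group, s.position, s.q, True)
                       for s in sites]
        active = [s for s in neutralized if not s.neutralized]
        assert bp.charge_dipole(
            [bp.PointCharge(s.q, s.position) for s in active]) \
            == pytest.approx(np.zeros(3))


@pytest.fixture(scope="module")
def cut_structure(saltbox_pdb):
    return bp.read_structure(saltbox_pdb)[0]


class TestEllipsoidCutoff:
    def _surface_point(self, structure, extra):
        pts = np.array([a.coords for a in structure.atoms])
        centre = pts.mean(axis=0)
        far = pts[np.argmax(np.linalg.norm(pts - centre, axis=1))]
        d = (far - centre) / np.linalg.norm(far - centre)
        return far + extra * d

    def test_water_near_surface_kept(self, cut_structure):
        structure = cut_structure
        w = EnvironmentSite("WATER", self._surface_point(structure, 4.0),
                            9.8 * np.eye(3), 0.0)
        kept = bp.ellipsoid_cutoff(structure, [w], 8.0)
        assert len(kept) == 1 and kept[0] is w

    def test_water_far_outside_dropped(self, cut_structure):
        structure = cut_structure
        w = EnvironmentSite("WATER", self._surface_point(structure, 30.0),
                            9.8 * np.eye(3), 0.0)
        assert bp.ellipsoid_cutoff(structure, [w], 8.0) == []

    def test_far_ion_kept_unconditionally(self, cut_structure):
        structure = cut_structure
        ion = _ion("CL", self._surface_point(structure, 30.0))
        kept = bp.ellipsoid_cutoff(structure, [ion], 8.0)
        assert len(kept) == 1 and kept[0] is ion

    def test_shrinking_cutoff_never_adds_waters(self, cut_structure):
        structure = cut_structure
        rng = np.random.default_rng(11)
        pts = np.array([a.coords for a in structure.atoms])
        centre = pts.mean(axis=0)
        waters = [EnvironmentSite("WATER",
                                  centre + rng.normal(scale=15.0, size=3),
                                  9.8 * np.eye(3), 0.0) for _ in range(60)]
        kept_small = {id(w) for w in bp.ellipsoid_cutoff(structure, waters, 3.0)}
        kept_large = {id(w) for w in bp.ellipsoid_cutoff(structure, waters, 9.0)}
        assert kept_small <= kept_large


class TestConfigurations:
    def test_seventy_total_with_pair_count_classes(self):
        configs = bp.enumerate_configurations()
        assert len(configs) == 70
        by_pairs = {k: sum(1 for c in configs if c.n_pairs == k)
                    for k in range(5)}
        assert by_pairs == {0: 1, 1: 16, 2: 36, 3: 16, 4: 1}

    def test_numbering_scheme(self):
        configs = bp.enumerate_configurations()
        assert configs[0].number == 1 and configs[0].name == "standard"
        assert configs[-1].number == 70 and configs[-1].name == "ABCDXYZW"
        one_pair = [c for c in configs if c.n_pairs == 1]
        assert [c.number for c in one_pair] == list(range(2, 18))
        assert [c.number for c in configs if c.n_pairs == 2] \
            == list(range(18, 54))
        assert [c.number for c in configs if c.n_pairs == 3] \
            == list(range(54, 70))

    def test_pairs_only_and_unique_names(self):
        configs = bp.enumerate_configurations()
        assert all(len(c.na_sites) == len(c.cl_sites) for c in configs)
        assert len({c.name for c in configs}) == 70
        assert all(set(c.na_sites) <= set(NA_LETTERS) for c in configs)
        assert all(set(c.cl_sites) <= set(CL_LETTERS) for c in configs)

    @pytest.mark.parametrize("na, cl, expected", [
        (("A", "C"), ("Z", "W"), "AC-ZW-"),
        ((), (), "standard"),
        (("A", "B", "C", "D"), ("X", "Y", "Z", "W"), "ABCDXYZW"),
        (("B",), ("X",), "B--X--"),
        (("C", "A"), ("W", "Z"), "AC-ZW-"),  # order of input letters irrelevant
    ])
    def test_config_names(self, na, cl, expected):
        assert bp.config_name(na, cl) == expected

    def test_unbalanced_sets_rejected(self):
        with pytest.raises(ValueError):
            bp.config_name(("A",), ())
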