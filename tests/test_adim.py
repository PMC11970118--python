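import numpy as np
import pytest

import blockpol as bp
from blockpol.adim import (
    DAMPING_SCHEMES,
    PolarizableSystem,
    damped_field_tensor,
    field_tensor,
    thole_screen,
)


def _system(positions, alphas, mu0=None, molecule_ids=None, f_ext=None):
    n = len(positions)
    return PolarizableSystem(
        site_ids=list(range(n)),
        positions=np.asarray(positions, float),
        alphas=np.asarray(alphas, float),
        mu0=np.zeros((n, 3)) if mu0 is None else np.asarray(mu0, float),
        molecule_ids=list(range(n)) if molecule_ids is None else molecule_ids,
        external_field=f_ext,
    )


def _random_system(rng, n, min_sep=6.0):
    """Well-separated random anisotropic sites for oracle comparisons."""
    positions = []
    while len(positions) < n:
        p = rng.uniform(-20, 20, 3)
        if all(np.linalg.norm(p - q) > min_sep for q in positions):
            positions.append(p)
    alphas = []
    for _ in range(n):
        q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
        alphas.append(q @ np.diag(rng.uniform(1, 12, 3)) @ q.T)
    mu0 = rng.normal(scale=0.5, size=(n, 3))
    f_ext = rng.normal(scale=0.01, size=(n, 3))
    return _system(positions, alphas, mu0=mu0, f_ext=f_ext)


class TestFieldTensor:
    def test_axial_closed_form(self):
        r = 4.0
        t = field_tensor([0, 0, r], [0, 0, 0])
        assert np.allclose(t, np.diag([-1, -1, 2]) / r**3)

    def test_traceless_and_symmetric(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(scale=5, size=(2, 3))
            t = field_tensor(a, b)
            assert abs(np.trace(t)) < 1e-12
            assert np.allclose(t, t.T)
            assert np.allclose(t, field_tensor(b, a))

    def test_matches_numerical_dipole_field_gradient(self):
        # independent oracle: T.mu equals the field of a point dipole mu,
        # obtained by numerical differentiation of its potential mu.r/r^3
        rng = np.random.default_rng(3)
        mu = np.array([0.3, -0.7, 0.2])
        site = np.array([2.0, 1.0, -3.0])

        def potential(x):
            r = x - site
            return mu @ r / np.linalg.norm(r)**3

        point = np.array([-1.0, 4.0, 2.0])
        h = 1e-5
        f_num = np.array([
            -(potential(point + h * e) - potential(point - h * e)) / (2 * h)
            for e in np.eye(3)])
        assert np.allclose(field_tensor(point, site) @ mu, f_num, atol=1e-8)


class TestTholeDamping:
    def test_long_range_limit_is_undamped(self):
        a, b_pt = np.array([0, 0, 30.0]), np.zeros(3)  # u = 2.6*30 / 1 = 78
        t_damped = damped_field_tensor(a, b_pt, 1.0, 1.0, b=2.6)
        t_bare = field_tensor(a, b_pt)
        assert np.linalg.norm(t_damped - t_bare) \
            < 1e-10 * np.linalg.norm(t_bare)

    def test_short_range_limit_vanishes(self):
        norms = []
        for r in (0.3, 0.1, 0.03, 0.01):
            t = damped_field_tensor([0, 0, r], [0, 0, 0], 1.0, 1.0, b=2.6)
            norms.append(np.linalg.norm(t))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.05  # screened tensor -> 0, no catastrophe

    def test_screen_monotone_increasing(self):
        u = np.linspace(0.0, 20.0, 400)
        s = np.array([thole_screen(x) for x in u])
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(s) > 0)
        assert s[-1] == pytest.approx(1.0, abs=1e-5)

    def test_zero_polarizability_site_is_undamped(self):
        a, b_pt = np.array([0, 0, 2.0]), np.zeros(3)
        t = damped_field_tensor(a, b_pt, 0.0, 1.0, b=2.6)
        assert np.allclose(t, field_tensor(a, b_pt))

    @pytest.mark.parametrize("scheme", sorted(DAMPING_SCHEMES))
    def test_all_schemes_finite_at_contact(self, scheme):
        if scheme == "none":
            return
        t = damped_field_tensor([0, 0, 0.5], [0, 0, 0], 1.0, 1.0,
                                b=2.6, scheme=scheme)
        assert np.all(np.isfinite(t))

    def test_no_singular_solve_at_half_bohr_contact(self):
        system = _system([[0, 0, 0], [0, 0, 0.5]],
                         [np.eye(3), np.eye(3)],
                         f_ext=np.tile([0.01, 0, 0], (2, 1)))
        result = bp.solve_induced(system, b=2.6)
        assert np.all(np.isfinite(result.dipoles))
        assert np.all(np.isfinite(result.total_alpha))


class TestSolveInduced:
    def test_single_site_linear_response(self):
        system = _system([[0, 0, 0]], [10.0 * np.eye(3)],
                         f_ext=[[0.01, 0, 0]])
        result = bp.solve_induced(system)
        assert np.allclose(result.induced_dipoles[0], [0.1, 0, 0])

    def test_full_intramolecular_exclusion_decouples_sites(self):
        rng = np.random.default_rng(4)
        n = 4
        alphas = [np.diag(rng.uniform(1, 5, 3)) for _ in range(n)]
        f = rng.normal(scale=0.02, size=(n, 3))
        system = _system(rng.normal(scale=4, size=(n, 3)), alphas,
                         molecule_ids=["mol"] * n, f_ext=f)
        result = bp.solve_induced(system)
        for i in range(n):
            assert np.allclose(result.induced_dipoles[i], alphas[i] @ f[i],
                               atol=1e-12)
            assert np.allclose(result.corrected_alphas[i], alphas[i],
                               atol=1e-12)

    def test_environment_free_system_returns_database_values(self):
        # all sites in one molecule, no external field: nothing changes
        rng = np.random.default_rng(6)
        mu0 = rng.normal(size=(3, 3))
        system = _system(rng.normal(scale=5, size=(3, 3)),
                         [np.eye(3)] * 3, mu0=mu0, molecule_ids=["p"] * 3)
        result = bp.solve_induced(system)
        assert np.allclose(result.dipoles, mu0, atol=1e-14)
        assert np.allclose(result.total_alpha, 3 * np.eye(3), atol=1e-14)

    def test_small_system_matches_explicit_inversion(self):
        # independent oracle: build the 3N x 3N linear system element by
        # element and invert it directly
        rng = np.random.default_rng(12)
        for n in (2, 3, 4, 5):
            system = _random_system(rng, n)
            result = bp.solve_induced(system, b=2.6)

            big = np.eye(3 * n)
            rhs = np.zeros(3 * n)
            for i in range(n):
                rhs[3 * i:3 * i + 3] = system.mu0[i] + \
                    system.alphas[i] @ system.external_field[i]
                for j in range(n):
                    if i == j:
                        continue
                    tij = damped_field_tensor(
                        system.positions[i], system.positions[j],
                        system.iso(i), system.iso(j), 2.6)
                    big[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= \
                        system.alphas[i] @ tij
            mu_oracle = np.linalg.solve(big, rhs).reshape(n, 3)
            assert np.allclose(result.dipoles, mu_oracle, atol=1e-10)

    def test_permutation_invariance_of_totals(self):
        rng = np.random.default_rng(13)
        system = _random_system(rng, 5)
        result = bp.solve_induced(system)
        perm = rng.permutation(5)
        shuffled = _system(system.positions[perm], system.alphas[perm],
                           mu0=system.mu0[perm],
                           f_ext=system.external_field[perm])
        result_p = bp.solve_induced(shuffled)
        assert np.allclose(result.dipoles.sum(axis=0),
                           result_p.dipoles.sum(axis=0), atol=1e-10)
        assert np.allclose(result.total_alpha, result_p.total_alpha, atol=1e-10)


class TestCorrectedPolarizabilities:
    def test_isolated_sites_unchanged(self):
        alphas = [np.diag([1.0, 2.0, 3.0]), 5.0 * np.eye(3)]
        system = _system([[0, 0, 0], [1e4, 0, 0]], alphas)
        per_site, total = bp.corrected_polarizabilities(system)
        assert np.allclose(per_site[0], alphas[0], atol=1e-9)
        assert np.allclose(total, alphas[0] + alphas[1], atol=1e-8)

    def test_silberstein_two_site_closed_form(self):
        # two isotropic alpha=1 sites at r=10 bohr along z, undamped:
        # alpha_par = 2a/(1 - 2a/r^3), alpha_perp = 2a/(1 + a/r^3)
        system = _system([[0, 0, 0], [0, 0, 10.0]], [np.eye(3), np.eye(3)])
        _, total = bp.corrected_polarizabilities(system, damping="none")
        a_par = 2.0 / (1.0 - 2.0 / 1000.0)
        a_perp = 2.0 / (1.0 + 1.0 / 1000.0)
        assert np.allclose(total, np.diag([a_perp, a_perp, a_par]), atol=1e-10)

    def test_small_system_matches_explicit_relay_inversion(self):
        rng = np.random.default_rng(21)
        for n in (2, 3, 5):
            system = _random_system(rng, n)
            per_site, total = bp.corrected_polarizabilities(system, b=2.6)

            big = np.zeros((3 * n, 3 * n))
            for i in range(n):
                big[3 * i:3 * i + 3, 3 * i:3 * i + 3] = \
                    np.linalg.inv(system.alphas[i])
                for j in range(n):
                    if i != j:
                        big[3 * i:3 * i + 3, 3 * j:3 * j + 3] = \
                            -damped_field_tensor(
                                system.positions[i], system.positions[j],
                                system.iso(i), system.iso(j), 2.6)
            relay = np.linalg.inv(big)
            oracle_total = sum(relay[3 * i:3 * i + 3, 3 * j:3 * j + 3]
                               for i in range(n) for j in range(n))
            oracle_site0 = sum(relay[0:3, 3 * j:3 * j + 3] for j in range(n))
            assert np.allclose(total, oracle_total, atol=1e-10)
            assert np.allclose(per_site[0], oracle_site0, atol=1e-10)

    def test_far_sodium_site_adds_its_isotropic_value(self):
        rng = np.random.default_rng(8)
        base = _random_system(rng, 3)
        _, total_base = bp.corrected_polarizabilities(base)
        with_na = _system(
            np.vstack([base.positions, [500.0, 0, 0]]),
            np.vstack([base.alphas, [0.3 * np.eye(3)]]),
        )
        _, total_na = bp.corrected_polarizabilities(with_na)
        assert np.allclose(total_na, total_base + 0.3 * np.eye(3), atol=1e-6)

    def test_corrections_decay_with_distance(self):
        alphas = [4.0 * np.eye(3), 4.0 * np.eye(3)]
        deviations = []
        for r in (8.0, 16.0, 32.0, 64.0):
            system = _system([[0, 0, 0], [0, 0, r]], alphas)
            _, total = bp.corrected_polarizabilities(system)
            deviations.append(np.linalg.norm(total - 8.0 * np.eye(3)))
        assert all(a > b for a, b in zip(deviations, deviations[1:]))
        # r^-3 rate: doubling r shrinks the deviation by ~8x
        assert deviations[1] / deviations[2] == pytest.approx(8.0, rel=0.1)

    def test_zero_tensor_site_excluded_from_relay(self):
        system = _system([[0, 0, 0], [0, 0, 6.0], [0, 0, 12.0]],
                         [np.eye(3), np.zeros((3, 3)), np.eye(3)])
        per_site, total = bp.corrected_polarizabilities(system, damping="none")
        assert np.allclose(per_site[1], np.zeros((3, 3)))
        assert np.all(np.isfinite(total))
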