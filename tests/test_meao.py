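from types import SimpleNamespace

import numpy as np
import pytest

from meaobond import meao
from meaobond.atomic_partition import AtomicPartition, build_partition
from meaobond.meao import (
    CoherenceTensorSource,
    MeanFieldSource,
    _block_expm,
    _param_index,
    _unpack,
    f_meao,
    f_meao_gradient,
    optimize_meao,
)


def trivial_partition(atom_of):
    atom_of = np.array(atom_of)
    n = len(atom_of)
    return AtomicPartition(
        np.eye(n), atom_of, [f"X{m}" for m in range(atom_of.max() + 1)],
        "iao-minimal", True, np.eye(n),
    )


def fd_gradient(source, part, eps=1e-5):
    pairs = _param_index(part)
    src = meao._as_source(source)
    out = {}
    for k, pq in enumerate(pairs):
        e = np.zeros(len(pairs))
        e[k] = eps
        up = _block_expm(_unpack(e, pairs, part.n_orbitals), part.blocks())
        um = _block_expm(_unpack(-e, pairs, part.n_orbitals), part.blocks())
        out[pq] = (f_meao(src.rotated(up), part) - f_meao(src.rotated(um), part)) / (
            2 * eps
        )
    return out


class TestObjective:
    def test_bond_state_value(self):
        """One orbital per atom, perfect bond: two coherences of 1/4 each."""
        from meaobond.engine.ci import CIWavefunction

        ci = np.full((2, 2), 0.5)
        wfn = CIWavefunction(2, (1, 1), ci, 0.0)
        # fix the sign structure of the bond state
        wfn.ci[1, 0] = 0.5
        part = trivial_partition([0, 1])
        src = CoherenceTensorSource(wfn.rdm2_ab())
        assert f_meao(src, part) == pytest.approx(0.125, abs=1e-12)

    def test_product_state_zero(self):
        part = trivial_partition([0, 1])
        assert f_meao(MeanFieldSource(np.diag([2.0, 0.0])), part) == pytest.approx(0.0)

    def test_mean_field_formula(self, two_atom_fixture):
        gamma, part = two_atom_fixture
        expect = sum(
            gamma[i, j] ** 4 / 8.0
            for i in range(4)
            for j in range(i + 1, 4)
            if part.atom_of[i] != part.atom_of[j]
        )
        assert f_meao(MeanFieldSource(gamma), part) == pytest.approx(expect, abs=1e-14)

    def test_global_phase_invariance(self):
        """The objective uses |coherence|^2 so a global wavefunction phase
        cannot change it: negate the CI vector."""
        from meaobond.engine.ci import CIWavefunction

        rng = np.random.default_rng(0)
        ci = rng.standard_normal((3, 3))
        ci /= np.linalg.norm(ci)
        part = trivial_partition([0, 0, 1])
        a = f_meao(CoherenceTensorSource(CIWavefunction(3, (1, 1), ci, 0.0).rdm2_ab()), part)
        b = f_meao(CoherenceTensorSource(CIWavefunction(3, (1, 1), -ci, 0.0).rdm2_ab()), part)
        assert a == pytest.approx(b, abs=1e-14)

    def test_dimension_mismatch(self):
        part = trivial_partition([0, 1])
        with pytest.raises(ValueError):
            f_meao(MeanFieldSource(np.eye(3)), part)


class TestGradient:
    def test_mean_field_fd(self, two_atom_fixture):
        gamma, part = two_atom_fixture
        g = f_meao_gradient(MeanFieldSource(gamma), part)
        fd = fd_gradient(MeanFieldSource(gamma), part)
        for (p, q), val in fd.items():
            assert abs(g[p, q] - val) < 1e-6

    def test_tensor_fd(self, rng):
        gab = rng.standard_normal((4, 4, 4, 4))
        part = trivial_partition([0, 0, 1, 1])
        g = f_meao_gradient(CoherenceTensorSource(gab), part)
        fd = fd_gradient(CoherenceTensorSource(gab), part)
        for (p, q), val in fd.items():
            assert abs(g[p, q] - val) < 1e-6

    def test_antisymmetric_and_blocked(self, two_atom_fixture):
        gamma, part = two_atom_fixture
        g = f_meao_gradient(MeanFieldSource(gamma), part)
        np.testing.assert_allclose(g, -g.T, atol=1e-14)
        mask = part.inter_center_mask()
        assert np.abs(g[mask]).max() == 0.0

    def test_stationary_at_optimum(self, two_atom_fixture):
        gamma, part = two_atom_fixture
        res = optimize_meao(MeanFieldSource(gamma), part, seed=3)
        u = np.eye(4)
        for b, ub in zip(part.blocks(), res.block_rotations):
            u[np.ix_(b, b)] = ub
        g = f_meao_gradient(MeanFieldSource(u.T @ gamma @ u), part)
        assert np.abs(g).max() < 1e-8


class TestOptimizer:
    def test_trivial_rotation_space(self, he2_mf):
        part = build_partition(he2_mf, "iao-minimal")
        src = MeanFieldSource(he2_mf.gamma_in(part.coefficients))
        res = optimize_meao(src, part, seed=0)
        np.testing.assert_allclose(
            res.partition.coefficients, part.coefficients, atol=1e-14
        )

    def test_grid_oracle(self, two_atom_fixture):
        """Exhaustive 2-angle grid search over the two block rotations."""
        gamma, part = two_atom_fixture
        res = optimize_meao(MeanFieldSource(gamma), part, seed=0)
        thetas = np.linspace(-np.pi / 2, np.pi / 2, 721)
        cs, sn = np.cos(thetas), np.sin(thetas)
        u = np.zeros((721, 2, 2))
        u[:, 0, 0] = cs
        u[:, 0, 1] = -sn
        u[:, 1, 0] = sn
        u[:, 1, 1] = cs
        d12 = gamma[:2, 2:]
        a = np.einsum("tab,bc->tac", u.transpose(0, 2, 1), d12)
        dcross = np.einsum("tac,scd->tsad", a, u)
        f_grid = (dcross**4).sum(axis=(2, 3)) / 8.0
        assert res.objective >= f_grid.max() - 1e-4

    def test_determinism(self, two_atom_fixture):
        gamma, part = two_atom_fixture
        r1 = optimize_meao(MeanFieldSource(gamma), part, seed=11)
        r2 = optimize_meao(MeanFieldSource(gamma), part, seed=11)
        assert r1.iteration_trace == r2.iteration_trace
        assert r1.objective == r2.objective
        assert r1.restart_index == r2.restart_index

    def test_monotone_accepted_values(self, two_atom_fixture):
        gamma, part = two_atom_fixture
        res = optimize_meao(MeanFieldSource(gamma), part, seed=2)
        vals = [v for _, v, _, _ in res.iteration_trace]
        assert all(b >= a - 1e-14 for a, b in zip(vals, vals[1:]))
        assert res.objective >= vals[0]

    def test_intra_atom_relabeling_invariance(self, two_atom_fixture):
        """Permuting orbitals within an atom (with the matching 1RDM
        transformation) cannot change the objective."""
        gamma, part = two_atom_fixture
        perm = np.array([1, 0, 2, 3])  # swap the two orbitals of atom A
        p = np.eye(4)[perm]
        val1 = f_meao(MeanFieldSource(gamma), part)
        val2 = f_meao(MeanFieldSource(p @ gamma @ p.T), part)
        assert val1 == pytest.approx(val2, abs=1e-14)


class TestInterCenterSum:
    def test_bond_state_single_pair(self):
        ci = np.full((2, 2), 0.5)
        sol = SimpleNamespace(ci=ci, norb=2, nelec=(1, 1))
        part = trivial_partition([0, 1])
        total = meao.inter_center_entanglement_sum(sol, part)
        assert total == pytest.approx(np.log(4), abs=1e-4)

    def test_product_state_zero(self):
        det = SimpleNamespace(gamma=np.diag([2.0, 0.0]), norb=2)
        part = trivial_partition([0, 1])
        assert meao.inter_center_entanglement_sum(det, part) == pytest.approx(
            0.0, abs=1e-5
        )


class TestThermalSource:
    def test_thermal_2rdm_meao_optimization(self, lih_mf):
        """Thermal opposite-spin 2RDM (lowest singlet + the three triplet
        components) drives the tensor-path optimizer starting from a
        meta-Lowdin partition."""
        from meaobond.atomic_partition import build_partition
        from meaobond.chem_backend import solve_cas, thermal_ensemble

        part = build_partition(lih_mf, "meta-lowdin")
        coeffs = part.coefficients
        n_elec = lih_mf.n_electrons
        singlet = solve_cas(lih_mf, coeffs, n_elec, nroots=2)
        t0 = solve_cas(lih_mf, coeffs, n_elec, nelec_spin=(3, 1))
        t1 = solve_cas(lih_mf, coeffs, n_elec, nelec_spin=(1, 3))
        # lowest four states: ground singlet + triply degenerate triplet
        states = [singlet[0], singlet[1], t0, t1]
        ens = thermal_ensemble(states, [s.energy for s in states])
        src = CoherenceTensorSource(ens.gab)
        res = optimize_meao(src, part, seed=0)
        assert res.objective >= f_meao(src, part) - 1e-12
        vals = [v for _, v, _, _ in res.iteration_trace]
        assert all(b >= a - 1e-14 for a, b in zip(vals, vals[1:]))

    def test_ground_state_dominates_at_low_temperature(self, lih_mf):
        from meaobond.atomic_partition import build_partition
        from meaobond.chem_backend import solve_cas, thermal_ensemble

        part = build_partition(lih_mf, "iao-minimal")
        roots = solve_cas(lih_mf, part.coefficients, lih_mf.n_electrons, nroots=2)
        ens = thermal_ensemble(roots, [r.energy for r in roots], beta=1e3)
        np.testing.assert_allclose(ens.gab, roots[0].gab, atol=1e-6)


class TestProxyFidelity:
    def test_proxy_optimum_concentrates_entanglement(self):
        """The coherence objective's maximizer is the basis in which one
        orbital pair carries the maximal attainable pairwise entanglement
        (log 4), i.e. the proxy finds the bonding pair.

        Note the literal statement "the proxy maximizer coincides with the
        maximizer of the summed pairwise entanglement" is refuted by direct
        grid evaluation: the *sum* over pairs is larger when a single bond is
        split across two half-bonds (pairwise relative entropy is not
        monogamous under this sum), so the faithful, checkable property is
        concentration, asserted here.
        """
        from meaobond.entanglement import relative_entropy_of_entanglement
        from meaobond.fock_rdm import two_orbital_rdm

        n = 4
        part = trivial_partition([0, 0, 1, 1])
        pairs = _param_index(part)
        # H2-like determinant: one doubly occupied homopolar bond orbital
        # with an admixture of the secondary function on each atom
        q = np.array([0.6, 0.3, 0.6, 0.3])
        q /= np.linalg.norm(q)
        gamma = 2.0 * np.outer(q, q)
        res = optimize_meao(MeanFieldSource(gamma), part, seed=0)
        u = np.eye(n)
        for b, ub in zip(part.blocks(), res.block_rotations):
            u[np.ix_(b, b)] = ub
        g_opt = u.T @ gamma @ u
        det = SimpleNamespace(gamma=g_opt, norb=n)
        best_pair = max(
            relative_entropy_of_entanglement(
                two_orbital_rdm(det, i, j).matrix, tol=1e-6
            )
            for i in (0, 1)
            for j in (2, 3)
        )
        # a single pair reaches the maximal attainable value
        assert best_pair == pytest.approx(np.log(4.0), abs=2e-3)
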