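from itertools import combinations
from types import SimpleNamespace

import numpy as np
import pytest

from meaobond import fock_rdm as fr
from meaobond.fockspace import string_list, two_orbital_reorder

from oracle import ci_to_dense, dense_partial_trace, entropy

LOG4 = np.log(4.0)


def random_ci(norb, nelec, seed=0):
    rng = np.random.default_rng(seed)
    na, nb = nelec
    ci = rng.standard_normal((len(string_list(norb, na)), len(string_list(norb, nb))))
    ci /= np.linalg.norm(ci)
    return SimpleNamespace(ci=ci, norb=norb, nelec=nelec)


class TestEntropy:
    def test_pure_projector(self):
        v = np.array([1.0, 2.0, 0.5, -1.0])
        v /= np.linalg.norm(v)
        assert fr.von_neumann_entropy(np.outer(v, v)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform(self):
        assert fr.von_neumann_entropy(np.eye(4) / 4) == pytest.approx(LOG4)

    def test_half(self):
        assert fr.von_neumann_entropy(np.diag([0.5, 0.5, 0, 0])) == pytest.approx(
            np.log(2)
        )

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            fr.von_neumann_entropy(np.diag([1.1, -0.1, 0.0, 0.0]))

    def test_non_hermitian_rejected(self):
        m = np.eye(4)
        m[0, 1] = 0.5
        with pytest.raises(ValueError):
            fr.von_neumann_entropy(m)


class TestCIPartialTraceOracle:
    """Exact agreement with brute-force dense partial traces (<= 8 spin
    orbitals)."""

    @pytest.mark.parametrize("norb,nelec", [(3, (2, 1)), (4, (2, 2)), (3, (1, 1))])
    def test_two_orbital_rdm(self, norb, nelec):
        sol = random_ci(norb, nelec, seed=42)
        psi = ci_to_dense(sol.ci, norb, nelec)
        reorder = two_orbital_reorder()
        for i, j in combinations(range(norb), 2):
            mine = fr.two_orbital_rdm(sol, i, j).matrix
            ref = dense_partial_trace(psi, 2 * norb, [2 * i, 2 * i + 1, 2 * j, 2 * j + 1])
            np.testing.assert_allclose(mine, reorder @ ref @ reorder.T, atol=1e-10)

    def test_bipartition_entropy(self):
        norb, nelec = 4, (2, 2)
        sol = random_ci(norb, nelec, seed=7)
        psi = ci_to_dense(sol.ci, norb, nelec)
        for subset in [(0,), (2,), (0, 1), (1, 3), (0, 2, 3)]:
            modes = [m for p in subset for m in (2 * p, 2 * p + 1)]
            ref = entropy(dense_partial_trace(psi, 2 * norb, modes))
            mine = fr.ci_bipartition_entropy(sol.ci, norb, nelec, list(subset))
            assert mine == pytest.approx(ref, abs=1e-10)


class TestOneOrbital:
    def test_doubly_occupied(self):
        # determinant with orbital 0 doubly occupied out of 2 orbitals
        ci = np.zeros((2, 2))
        ci[0, 0] = 1.0  # alpha string 0b01, beta string 0b01
        sol = SimpleNamespace(ci=ci, norb=2, nelec=(1, 1))
        np.testing.assert_allclose(
            fr.one_orbital_rdm(sol, 0).matrix, np.diag([0, 0, 0, 1.0]), atol=1e-14
        )
        np.testing.assert_allclose(
            fr.one_orbital_rdm(sol, 1).matrix, np.diag([1.0, 0, 0, 0]), atol=1e-14
        )

    def test_bond_state_orbital(self, bond_ci=None):
        from meaobond.model_systems import bond_state

        sol = SimpleNamespace(matrix=None)
        rho = fr.TwoOrbitalRDM(bond_state().density_matrix())
        np.testing.assert_allclose(
            rho.partial_trace(0).matrix, np.eye(4) / 4, atol=1e-12
        )

    def test_index_errors(self):
        sol = random_ci(3, (2, 1))
        with pytest.raises(IndexError):
            fr.one_orbital_rdm(sol, 3)
        with pytest.raises(ValueError):
            fr.two_orbital_rdm(sol, 1, 1)


class TestGaussianRoute:
    def test_determinant_matches_ci_route(self):
        """A closed-shell determinant's reduced states from the 1RDM alone
        must equal the exact CI partial trace."""
        norb = 3
        ci = np.zeros((3, 3))
        ci[0, 0] = 1.0  # alpha, beta strings 0b011: orbitals 0,1 occupied
        sol = SimpleNamespace(ci=ci, norb=norb, nelec=(2, 2))
        det_axis = SimpleNamespace(gamma=np.diag([2.0, 2.0, 0.0]), norb=norb)
        for i, j in combinations(range(norb), 2):
            a = fr.two_orbital_rdm(det_axis, i, j).matrix
            b = fr.two_orbital_rdm(sol, i, j).matrix
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_rotated_determinant(self):
        """Gaussian route vs CI route for a rotated (correlation-free) state."""
        theta = 0.7
        u = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        gamma = 2.0 * np.outer(u[:, 0], u[:, 0])
        det = SimpleNamespace(gamma=gamma, norb=2)
        # CI vector of the same state: expand |phi phi-bar> determinant
        c0, c1 = u[0, 0], u[1, 0]
        # b+ = c0 a0+ + c1 a1+; |b_up b_dn> in (na, nb) = (1, 1) block
        ci = np.array([[c0 * c0, c0 * c1], [c1 * c0, c1 * c1]])
        sol = SimpleNamespace(ci=ci, norb=2, nelec=(1, 1))
        a = fr.two_orbital_rdm(det, 0, 1).matrix
        b = fr.two_orbital_rdm(sol, 0, 1).matrix
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestMixedAndMutualInformation:
    def test_component_averaging(self):
        s1 = random_ci(3, (2, 1), seed=1)
        s2 = random_ci(3, (2, 1), seed=2)
        mix = SimpleNamespace(components=[(0.3, s1), (0.7, s2)], norb=3)
        m = fr.two_orbital_rdm(mix, 0, 1).matrix
        ref = 0.3 * fr.two_orbital_rdm(s1, 0, 1).matrix + 0.7 * fr.two_orbital_rdm(
            s2, 0, 1
        ).matrix
        np.testing.assert_allclose(m, ref, atol=1e-12)

    def test_product_state_zero(self):
        det = SimpleNamespace(gamma=np.diag([2.0, 0.0]), norb=2)
        assert fr.mutual_information(det, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_bond_state_maximal(self):
        from meaobond.model_systems import bond_state

        ci = np.zeros((2, 2))
        # bond state in the (1,1) sector of 2 orbitals
        ci[0, 0] = 0.5   # both on orbital 0 -> |updn, 0>
        ci[1, 1] = 0.5   # both on orbital 1 -> |0, updn>
        ci[0, 1] = 0.5   # alpha on 0, beta on 1 -> |up, dn>
        ci[1, 0] = 0.5   # alpha on 1, beta on 0 -> -|dn, up>
        sol = SimpleNamespace(ci=ci, norb=2, nelec=(1, 1))
        np.testing.assert_allclose(
            fr.two_orbital_rdm(sol, 0, 1).matrix,
            bond_state().density_matrix().real,
            atol=1e-12,
        )
        assert fr.mutual_information(sol, 0, 1) == pytest.approx(2 * LOG4, abs=1e-12)

    def test_superselection_blocks(self):
        sol = random_ci(4, (2, 2), seed=11)
        for i, j in [(0, 1), (1, 3)]:
            assert fr.two_orbital_rdm(sol, i, j).off_sector_norm() < 1e-10

    def test_partial_trace_consistency(self):
        sol = random_ci(4, (2, 2), seed=5)
        rho = fr.two_orbital_rdm(sol, 1, 2)
        np.testing.assert_allclose(
            rho.partial_trace(0).matrix,
            fr.one_orbital_rdm(sol, 1).matrix,
            atol=1e-10,
        )
        assert np.trace(rho.matrix) == pytest.approx(1.0, abs=1e-12)


def test_hdf5_roundtrip(tmp_path):
    sol = random_ci(3, (2, 1), seed=8)
    rho2 = fr.two_orbital_rdm(sol, 0, 1)
    rho1 = fr.one_orbital_rdm(sol, 2)
    path = tmp_path / "rdms.h5"
    fr.save_rdms_hdf5(path, {"pair01": rho2, "orb2": rho1})
    back = fr.load_rdms_hdf5(path)
    np.testing.assert_allclose(back["pair01"].matrix, rho2.matrix, atol=1e-15)
    np.testing.assert_allclose(back["orb2"].matrix, rho1.matrix, atol=1e-15)
    assert back["pair01"].off_sector_norm() == rho2.off_sector_norm()


def test_named_coherences_equal_2rdm_elements():
    """The two bond coherences of the two-orbital RDM equal the opposite-spin
    2RDM elements under the package's fixed operator ordering: the
    number-exchange coherence with sign +1, the spin-exchange one with -1."""
    from meaobond.engine.ci import CIWavefunction

    rng = np.random.default_rng(0)
    for norb, nelec in [(3, (2, 1)), (4, (2, 2))]:
        na, nb = nelec
        ci = rng.standard_normal(
            (len(string_list(norb, na)), len(string_list(norb, nb)))
        )
        ci /= np.linalg.norm(ci)
        wfn = CIWavefunction(norb, nelec, ci, 0.0)
        dab = wfn.rdm2_ab()
        for i, j in combinations(range(norb), 2):
            rho = fr.two_orbital_rdm(wfn, i, j).matrix
            assert rho[3, 12] == pytest.approx(dab[i, i, j, j], abs=1e-12)
            assert rho[6, 9] == pytest.approx(-dab[i, j, j, i], abs=1e-12)
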