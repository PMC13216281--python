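from types import SimpleNamespace

import numpy as np
import pytest

from meaobond import entanglement as ent
from meaobond import model_systems as ms
from meaobond.fockspace import string_list

LOG2, LOG3, LOG4 = np.log(2.0), np.log(3.0), np.log(4.0)


def embed_qubits_in_spin_sector(rho2q: np.ndarray) -> np.ndarray:
    """Embed a two-qubit state into two orbital Fock spaces using the N=1
    sector {|up>, |dn>} of each factor (physical spin qubits)."""
    out = np.zeros((16, 16), complex)
    for a in range(2):
        for b in range(2):
            for c in range(2):
                for d in range(2):
                    out[4 * (a + 1) + (b + 1), 4 * (c + 1) + (d + 1)] = rho2q[
                        2 * a + b, 2 * c + d
                    ]
    return out


def bell_diagonal(p: float) -> np.ndarray:
    phip = np.array([1, 0, 0, 1]) / np.sqrt(2)
    phim = np.array([1, 0, 0, -1]) / np.sqrt(2)
    psip = np.array([0, 1, 1, 0]) / np.sqrt(2)
    psim = np.array([0, 1, -1, 0]) / np.sqrt(2)
    w = [p, (1 - p) / 3, (1 - p) / 3, (1 - p) / 3]
    return sum(wi * np.outer(v, v) for wi, v in zip(w, [phip, phim, psip, psim]))


def bell_ree_exact(p: float) -> float:
    if p <= 0.5:
        return 0.0
    if p >= 1.0:
        return LOG2
    return LOG2 + p * np.log(p) + (1 - p) * np.log(1 - p)


class TestPureBipartite:
    def test_bond_state(self):
        assert ent.pure_bipartite_entanglement(ms.bond_state(), (4, 4)) == pytest.approx(
            LOG4, abs=1e-12
        )

    def test_product_state(self):
        psi = np.zeros(16)
        psi[12] = 1.0
        assert ent.pure_bipartite_entanglement(psi, (4, 4)) == pytest.approx(0.0, abs=1e-12)

    def test_ghz_one_qubit(self):
        assert ent.pure_bipartite_entanglement(
            ms.ghz_state(3).amplitudes, (2, 4)
        ) == pytest.approx(LOG2, abs=1e-12)

    def test_mixed_input_rejected(self):
        with pytest.raises(TypeError):
            ent.pure_bipartite_entanglement(np.eye(16) / 16, (4, 4))


class TestRelativeEntropyOfEntanglement:
    def test_separable_diagonal_mixture(self):
        rng = np.random.default_rng(0)
        d = rng.random(16)
        d /= d.sum()
        assert ent.relative_entropy_of_entanglement(np.diag(d)) == pytest.approx(
            0.0, abs=1e-5
        )

    @pytest.mark.parametrize("sep", ["number-superselected", "unrestricted"])
    def test_pure_bond_projector(self, sep):
        v = ent.relative_entropy_of_entanglement(
            ms.bond_state().density_matrix(), separable_set=sep
        )
        assert v == pytest.approx(LOG4, abs=1e-4)

    @pytest.mark.parametrize("p", [0.55, 0.7, 0.9, 1.0])
    @pytest.mark.parametrize("sep", ["number-superselected", "unrestricted"])
    def test_bell_diagonal_closed_form(self, p, sep):
        """Spin-sector embedding keeps both separable sets equivalent to the
        plain two-qubit problem, so the closed form applies to each."""
        rho = embed_qubits_in_spin_sector(bell_diagonal(p))
        v = ent.relative_entropy_of_entanglement(rho, separable_set=sep)
        assert v == pytest.approx(bell_ree_exact(p), abs=1e-3)

    def test_upper_bounded_by_mutual_information(self):
        from meaobond.fock_rdm import mutual_information, two_orbital_rdm

        rng = np.random.default_rng(2)
        ci = rng.standard_normal((3, 3))
        ci /= np.linalg.norm(ci)
        sol = SimpleNamespace(ci=ci, norb=3, nelec=(1, 1))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            rho = two_orbital_rdm(sol, i, j)
            e = ent.relative_entropy_of_entanglement(rho.matrix)
            assert e <= mutual_information(sol, i, j) + 1e-6

    def test_sector_diagonal_closed_form(self):
        rho = ms.bond_state().density_matrix()
        v = ent.relative_entropy_of_entanglement(rho, separable_set="sector-diagonal")
        # nearest diagonal state: S(diag rho) - S(rho) = log 4
        assert v == pytest.approx(LOG4, abs=1e-10)

    def test_direct_product_mixture_oracle(self):
        """Rank-2 mixed state: the Frank-Wolfe solver must agree with a direct
        nonlinear minimization over an explicit product-state mixture."""
        rng = np.random.default_rng(5)
        v1 = ms.bond_state().coefficients.real
        v2 = np.zeros(16)
        v2[1] = v2[4] = 1 / np.sqrt(2)
        rho = 0.7 * np.outer(v1, v1) + 0.3 * np.outer(v2, v2)
        target = ent.relative_entropy_of_entanglement(
            rho, separable_set="unrestricted", tol=1e-7
        )
        tr_rr = ent._rel_entropy_terms(rho.astype(complex))

        from scipy.optimize import minimize

        n_terms = 16  # complex product states: the optimum genuinely needs them

        def unpack(x):
            w = np.exp(x[:n_terms])
            w /= w.sum()
            re = x[n_terms : n_terms * 9].reshape(n_terms, 2, 4)
            im = x[n_terms * 9 :].reshape(n_terms, 2, 4)
            sigma = np.zeros((16, 16), complex)
            for k in range(n_terms):
                a = re[k, 0] + 1j * im[k, 0]
                b = re[k, 1] + 1j * im[k, 1]
                v = np.kron(a / np.linalg.norm(a), b / np.linalg.norm(b))
                sigma += w[k] * np.outer(v, v.conj())
            return sigma

        def fun(x):
            return ent._objective(rho.astype(complex), unpack(x), tr_rr)

        best = np.inf
        for s in range(3):
            x0 = np.concatenate(
                [np.zeros(n_terms), np.random.default_rng(s).standard_normal(n_terms * 16)]
            )
            res = minimize(fun, x0, method="L-BFGS-B", options={"maxiter": 3000})
            best = min(best, res.fun)
        assert target == pytest.approx(best, abs=1e-3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ent.relative_entropy_of_entanglement(np.eye(9) / 9, dims=(4, 4))


class TestGME:
    def test_ghz(self):
        r = ent.gme(ms.ghz_state(3))
        assert r.value == pytest.approx(LOG2, abs=1e-12)
        assert r.normalized == pytest.approx(1.0, abs=1e-12)
        assert len(r.minimizing_subset) in (1, 2)

    def test_w(self):
        r = ent.gme(ms.w_state(3))
        assert r.value == pytest.approx(LOG3 - 2 / 3 * LOG2, abs=1e-12)

    def test_ghz_pairs_unentangled(self):
        """Tracing one qubit from GHZ leaves a separable two-qubit state."""
        amp = ms.ghz_state(3).amplitudes.reshape(2, 2, 2)
        m = amp.reshape(4, 2)
        rho_pair = m @ m.conj().T
        v = ent.relative_entropy_of_entanglement(
            rho_pair, dims=(2, 2), separable_set="unrestricted"
        )
        assert v == pytest.approx(0.0, abs=1e-5)

    def test_w_pairs_entangled(self):
        amp = ms.w_state(3).amplitudes.reshape(2, 2, 2)
        m = amp.reshape(4, 2)
        rho_pair = m @ m.conj().T
        v = ent.relative_entropy_of_entanglement(
            rho_pair, dims=(2, 2), separable_set="unrestricted"
        )
        assert v > 0.05

    def test_biseparable_zero(self):
        # product of a Bell pair on qubits (0,1) and |0> on qubit 2
        bell = np.array([1, 0, 0, 1]) / np.sqrt(2)
        amp = np.kron(bell, np.array([1.0, 0.0]))
        r = ent.gme(ms.QubitRegisterState(amp))
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_below_cuts(self):
        rng = np.random.default_rng(9)
        for k in (4, 5):
            amp = rng.standard_normal(2**k)
            amp /= np.linalg.norm(amp)
            state = ms.QubitRegisterState(amp)
            ex = ent.gme(state, mode="exhaustive")
            cuts = ent.gme(state, mode="mps-cuts")
            assert ex.value <= cuts.value + 1e-12
            assert ex.n_bipartitions == 2 ** (k - 1) - 1

    def test_ci_state(self):
        ci = np.zeros((2, 2))
        ci[0, 0] = ci[1, 1] = ci[0, 1] = 0.5
        ci[1, 0] = 0.5
        sol = SimpleNamespace(ci=ci, norb=2, nelec=(1, 1))
        r = ent.gme(sol)
        assert r.value == pytest.approx(LOG4, abs=1e-12)
        assert r.normalized == pytest.approx(1.0, abs=1e-12)

    def test_mixed_rejected(self):
        with pytest.raises(TypeError):
            ent.gme(np.eye(8) / 8)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            ent.gme(ms.ghz_state(3), mode="nope")
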