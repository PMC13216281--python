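"""Restricted Hartree-Fock with density fitting (RI-JK) and DIIS."""

from __future__ import annotations

import numpy as np
import scipy.linalg

from . import integrals
from .mole import Molecule

__all__ = ["RHF", "SCFConvergenceError"]


class SCFConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class _DIIS:
    def __init__(self, space=8):
        self.space = space
        self.errs: list[np.ndarray] = []
        self.focks: list[np.ndarray] = []

    def update(self, fock, err):
        self.errs.append(err.ravel())
        self.focks.append(fock.copy())
        if len(self.errs) > self.space:
            self.errs.pop(0)
            self.focks.pop(0)
        n = len(self.errs)
        if n < 2:
            return fock
        b = -np.ones((n + 1, n + 1))
        b[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                b[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(b, rhs)[:n]
        except np.linalg.LinAlgError:
            return fock
        return sum(ci * fi for ci, fi in zip(c, self.focks))


class RHF:
    """Closed-shell Hartree-Fock backed by density-fitted J/K builds.

    The whitened three-center tensor ``b`` (nao, nao, naux) satisfies
    (uv|kl) ~= sum_P b[u,v,P] b[k,l,P] and is reused for integral transforms
    downstream (CASCI active-space Hamiltonians).
    """

    def __init__(
        self,
        mol: Molecule,
        auxbasis: str = "def2-universal-jkfit",
        conv_tol: float = 1e-9,
        max_cycle: int = 120,
        level_shift: float = 0.0,
    ):
        if mol.nelectron % 2:
            raise ValueError("RHF requires an even electron count")
        self.mol = mol
        self.aux = mol.with_basis(auxbasis)
        self.conv_tol = conv_tol
        self.max_cycle = max_cycle
        self.level_shift = level_shift
        self.converged = False
        self.e_tot = None
        self.mo_coeff = None
        self.mo_energy = None
        self.iteration_trace: list[tuple[int, float, float]] = []
        self._build_integrals()

    def _build_integrals(self):
        mol = self.mol
        self.s = integrals.overlap(mol)
        self.hcore = integrals.kinetic(mol) + integrals.nuclear_attraction(mol)
        j2c = integrals.coulomb_2c(self.aux)
        j3c = integrals.coulomb_3c(mol, self.aux)
        # whiten: b = (uv|P) L^-T with (P|Q) = L L^T
        lchol = scipy.linalg.cholesky(
            j2c + 1e-12 * np.eye(len(j2c)), lower=True
        )
        nao, _, naux = j3c.shape
        flat = j3c.reshape(nao * nao, naux)
        b = scipy.linalg.solve_triangular(lchol, flat.T, lower=True).T
        self.b = np.ascontiguousarray(b.reshape(nao, nao, naux))
        self.e_nuc = mol.nuclear_repulsion()

    # -- J/K builds --------------------------------------------------------

    def get_j(self, dm: np.ndarray) -> np.ndarray:
        rho = np.tensordot(self.b, dm, axes=([0, 1], [0, 1]))
        return np.tensordot(self.b, rho, axes=(2, 0))

    def get_k_occ(self, c_occ: np.ndarray) -> np.ndarray:
        """Exchange of the density 2*C_occ C_occ^T."""
        t = np.tensordot(self.b, c_occ, axes=(1, 0))  # (nao, naux, nocc)
        nao = t.shape[0]
        tm = t.transpose(0, 2, 1).reshape(nao, -1)
        return 2.0 * (tm @ tm.T)

    def get_k(self, dm: np.ndarray) -> np.ndarray:
        """Exchange for a general symmetric density (via its eigenvectors)."""
        w, v = np.linalg.eigh(dm)
        keep = np.abs(w) > 1e-12
        c = v[:, keep] * np.sqrt(np.abs(w[keep]))
        signs = np.sign(w[keep])
        t = np.tensordot(self.b, c, axes=(1, 0))
        nao, naux, nvec = t.shape
        k = np.zeros((nao, nao))
        for i in range(nvec):
            k += signs[i] * (t[:, :, i] @ t[:, :, i].T)
        return k

    # -- SCF loop ----------------------------------------------------------

    def _initial_fock(self):
        # generalized Wolfsberg-Helmholz guess
        hd = np.diag(self.hcore)
        f = 0.875 * self.s * (hd[:, None] + hd[None, :])
        np.fill_diagonal(f, hd)
        return f

    def kernel(self) -> float:
        nocc = self.mol.nelectron // 2
        s = self.s
        f = self._initial_fock()
        diis = _DIIS()
        e_old = 0.0
        dm = None
        for it in range(1, self.max_cycle + 1):
            mo_e, mo_c = scipy.linalg.eigh(f, s)
            c_occ = mo_c[:, :nocc]
            dm = 2.0 * c_occ @ c_occ.T
            j = self.get_j(dm)
            k = self.get_k_occ(c_occ)
            f_new = self.hcore + j - 0.5 * k
            e_elec = 0.5 * np.sum(dm * (self.hcore + f_new))
            e_tot = e_elec + self.e_nuc
            err = f_new @ dm @ s - s @ dm @ f_new
            f = diis.update(f_new, err)
            if self.level_shift:
                f = f + self.level_shift * (s - s @ dm @ s / 2.0)
            de = abs(e_tot - e_old)
            gnorm = np.abs(err).max()
            self.iteration_trace.append((it, float(e_tot), float(gnorm)))
            if de < self.conv_tol and gnorm < 1e-6:
                self.converged = True
                self.e_tot = float(e_tot)
                self.mo_energy, self.mo_coeff = mo_e, mo_c
                self.mo_occ = np.zeros(len(mo_e))
                self.mo_occ[:nocc] = 2.0
                return self.e_tot
            e_old = e_tot
        raise SCFConvergenceError(
            f"SCF did not converge in {self.max_cycle} cycles "
            f"(last dE={de:.2e}, |FDS-SDF|={gnorm:.2e})",
            trace=self.iteration_trace,
        )

    # -- results -----------------------------------------------------------

    def density_matrix(self) -> np.ndarray:
        nocc = self.mol.nelectron // 2
        c_occ = self.mo_coeff[:, :nocc]
        return 2.0 * c_occ @ c_occ.T

    def mo_transform_b(self, c_left: np.ndarray, c_right: np.ndarray) -> np.ndarray:
        """Whitened 3-center tensor in a (left, right) MO pair basis."""
        t = np.tensordot(c_left.T, self.b, axes=(1, 0))
        return np.tensordot(t, c_right, axes=(1, 0)).transpose(0, 2, 1)

    def active_space_hamiltonian(self, c_act: np.ndarray, c_closed: np.ndarray):
        """Effective (h_act, eri_act, e_core) with closed orbitals doubly
        occupied; all coefficient matrices are over the AO basis."""
        dm_core = 2.0 * c_closed @ c_closed.T if c_closed.shape[1] else np.zeros_like(self.s)
        j = self.get_j(dm_core)
        k = self.get_k_occ(c_closed) if c_closed.shape[1] else np.zeros_like(self.s)
        f_core = self.hcore + j - 0.5 * k
        e_core = 0.5 * np.sum(dm_core * (self.hcore + f_core)) + self.e_nuc
        h_act = c_act.T @ f_core @ c_act
        b_act = self.mo_transform_b(c_act, c_act)
        eri_act = np.tensordot(b_act, b_act, axes=(2, 2))
        return h_act, eri_act, float(e_core)
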