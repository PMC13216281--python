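"""Determinant (string-based) full CI for small active spaces.

Determinants are (alpha string, beta string) pairs; a determinant applies all
alpha creation operators (orbital ascending) before all beta ones.  String
ordering comes from :func:`meaobond.fockspace.string_list` and is shared with
the CI-vector partial-trace machinery.

The sigma algorithm is the dense-intermediate variant: T[p,q] = E_pq |C> is
materialized as a (norb, norb, Na, Nb) array, which is comfortable for the
<= 10-orbital active spaces this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse.linalg

from ..fockspace import string_list

__all__ = ["CIWavefunction", "solve_fci", "SolverError"]


class SolverError(RuntimeError):
    pass


@lru_cache(maxsize=64)
def _excitation_table(norb: int, nelec: int):
    """Rows (istr, p, q, jstr, sign) enumerating E_pq |str> for one spin."""
    strings = string_list(norb, nelec)
    index = -np.ones(1 << norb, dtype=np.int64)
    index[strings] = np.arange(len(strings))
    rows_i, rows_p, rows_q, rows_j, rows_s = [], [], [], [], []
    for i, st in enumerate(strings):
        st = int(st)
        for q in range(norb):
            if not (st >> q) & 1:
                continue
            m1 = st ^ (1 << q)
            sgn_q = 1 - 2 * (bin(st & ((1 << q) - 1)).count("1") & 1)
            for p in range(norb):
                if (m1 >> p) & 1:
                    continue
                new = m1 | (1 << p)
                sgn_p = 1 - 2 * (bin(m1 & ((1 << p) - 1)).count("1") & 1)
                rows_i.append(i)
                rows_p.append(p)
                rows_q.append(q)
                rows_j.append(index[new])
                rows_s.append(sgn_q * sgn_p)
    return (
        np.array(rows_i, dtype=np.int64),
        np.array(rows_p, dtype=np.int64),
        np.array(rows_q, dtype=np.int64),
        np.array(rows_j, dtype=np.int64),
        np.array(rows_s, dtype=np.float64),
        len(strings),
    )


def _apply_epq_all(c: np.ndarray, norb: int, nelec) -> np.ndarray:
    """T[p,q] = (E^alpha_pq + E^beta_pq) |C>, shape (norb, norb, Na, Nb)."""
    na, nb = nelec
    ia, pa, qa, ja, sa, num_a = _excitation_table(norb, na)
    ib, pb, qb, jb, sb, num_b = _excitation_table(norb, nb)
    t = np.zeros((norb, norb, num_a, num_b))
    flat = t.reshape(norb * norb * num_a, num_b)
    np.add.at(flat, (pa * norb + qa) * num_a + ja, sa[:, None] * c[ia, :])
    tt = np.zeros((norb, norb, num_b, num_a))
    flat_b = tt.reshape(norb * norb * num_b, num_a)
    np.add.at(flat_b, (pb * norb + qb) * num_b + jb, sb[:, None] * c.T[ib, :])
    t += tt.transpose(0, 1, 3, 2)
    return t


def _apply_epq_weighted(g: np.ndarray, norb: int, nelec) -> np.ndarray:
    """sum_pq E_pq |G[p,q]> for a stack of vectors G (norb, norb, Na, Nb)."""
    na, nb = nelec
    ia, pa, qa, ja, sa, num_a = _excitation_table(norb, na)
    ib, pb, qb, jb, sb, num_b = _excitation_table(norb, nb)
    out = np.zeros(g.shape[2:])
    np.add.at(out, ja, sa[:, None] * g[pa, qa, ia, :])
    outt = np.zeros((g.shape[3], g.shape[2]))
    gt = g.transpose(0, 1, 3, 2)
    np.add.at(outt, jb, sb[:, None] * gt[pb, qb, ib, :])
    return out + outt.T


def _h_diagonal(h1e, eri, norb, nelec) -> np.ndarray:
    na, nb = nelec
    occ_a = _occ_matrix(norb, na)
    occ_b = _occ_matrix(norb, nb)
    hd = np.diag(h1e)
    jm = np.einsum("ppqq->pq", eri)
    km = np.einsum("pqqp->pq", eri)
    ea = occ_a @ hd
    eb = occ_b @ hd
    jaa = 0.5 * np.einsum("ip,pq,iq->i", occ_a, jm, occ_a)
    jbb = 0.5 * np.einsum("ip,pq,iq->i", occ_b, jm, occ_b)
    jab = occ_a @ jm @ occ_b.T
    kaa = 0.5 * np.einsum("ip,pq,iq->i", occ_a, km, occ_a)
    kbb = 0.5 * np.einsum("ip,pq,iq->i", occ_b, km, occ_b)
    diag = (
        ea[:, None]
        + eb[None, :]
        + jaa[:, None]
        + jbb[None, :]
        + jab
        - kaa[:, None]
        - kbb[None, :]
    )
    return diag


def _occ_matrix(norb, nelec):
    strings = string_list(norb, nelec)
    occ = np.zeros((len(strings), norb))
    for i, st in enumerate(strings):
        for p in range(norb):
            occ[i, p] = (int(st) >> p) & 1
    return occ


@dataclass
class CIWavefunction:
    """A CI solution in an orthonormal orbital basis."""

    norb: int
    nelec: tuple[int, int]
    ci: np.ndarray
    energy: float

    @property
    def shape(self):
        return self.ci.shape

    def gamma(self) -> np.ndarray:
        """Spin-free 1RDM gamma[p,q] = sum_sigma <f+_p,sigma f_q,sigma>."""
        t = _apply_epq_all(self.ci, self.norb, self.nelec)
        g = np.tensordot(t, self.ci, axes=([2, 3], [0, 1]))
        return 0.5 * (g + g.T)

    def gamma_spin(self) -> np.ndarray:
        """Per-spin 1RDM (restricted solutions only use gamma/2; kept general)."""
        na, nb = self.nelec
        ia, pa, qa, ja, sa, num_a = _excitation_table(self.norb, na)
        t = np.zeros((self.norb, self.norb, num_a, self.ci.shape[1]))
        flat = t.reshape(self.norb * self.norb * num_a, self.ci.shape[1])
        np.add.at(flat, (pa * self.norb + qa) * num_a + ja, sa[:, None] * self.ci[ia, :])
        return np.tensordot(t, self.ci, axes=([2, 3], [0, 1]))

    def rdm2_ab(self) -> np.ndarray:
        """Opposite-spin 2RDM D[p,q,r,s] = <f+_p,up f+_q,dn f_s,dn f_r,up>."""
        norb, (na, nb) = self.norb, self.nelec
        ia, pa, qa, ja, sa, num_a = _excitation_table(norb, na)
        ib, pb, qb, jb, sb, num_b = _excitation_table(norb, nb)
        ta = np.zeros((norb, norb, num_a, num_b))
        flat = ta.reshape(norb * norb * num_a, num_b)
        np.add.at(flat, (pa * norb + qa) * num_a + ja, sa[:, None] * self.ci[ia, :])
        tb = np.zeros((norb, norb, num_b, num_a))
        flat_b = tb.reshape(norb * norb * num_b, num_a)
        np.add.at(flat_b, (pb * norb + qb) * num_b + jb, sb[:, None] * self.ci.T[ib, :])
        tb = tb.transpose(0, 1, 3, 2)
        # <E^a_pr E^b_qs> = <E^a_rp C | E^b_qs C>
        return np.einsum("rpIJ,qsIJ->pqrs", ta, tb, optimize=True)

    def overlap(self, other: "CIWavefunction") -> float:
        return float(np.sum(self.ci * other.ci))


def solve_fci(
    h1e: np.ndarray,
    eri: np.ndarray,
    norb: int,
    nelec,
    nroots: int = 1,
    ecore: float = 0.0,
    dense_cutoff: int = 1200,
) -> list[CIWavefunction]:
    """Lowest ``nroots`` eigenstates of the active-space Hamiltonian.

    ``eri`` is the chemist-notation (pq|rs) array.  Small problems are solved
    densely; larger ones with implicitly-restarted Lanczos on the sigma
    operator (deterministic start vector).
    """
    if isinstance(nelec, int):
        na = (nelec + 1) // 2
        nb = nelec - na
        nelec = (na, nb)
    na, nb = nelec
    if not (0 <= na <= norb and 0 <= nb <= norb):
        raise SolverError(f"invalid electron count {nelec} for {norb} orbitals")
    h1e = np.asarray(h1e, float)
    eri = np.asarray(eri, float)
    heff = h1e - 0.5 * np.einsum("pqqs->ps", eri)
    num_a = len(string_list(norb, na))
    num_b = len(string_list(norb, nb))
    dim = num_a * num_b

    def sigma(cvec):
        c = cvec.reshape(num_a, num_b)
        t = _apply_epq_all(c, norb, nelec)
        out = np.tensordot(heff, t, axes=([0, 1], [0, 1]))
        g = (
            eri.reshape(norb * norb, norb * norb)
            @ t.reshape(norb * norb, num_a * num_b)
        ).reshape(norb, norb, num_a, num_b)
        out = out + 0.5 * _apply_epq_weighted(g, norb, nelec)
        return out.ravel()

    nroots = min(nroots, dim)
    if dim <= dense_cutoff:
        hmat = np.zeros((dim, dim))
        for k in range(dim):
            e = np.zeros(dim)
            e[k] = 1.0
            hmat[:, k] = sigma(e)
        evals, evecs = np.linalg.eigh(hmat)
    else:
        diag = _h_diagonal(h1e, eri, norb, nelec).ravel()
        v0 = np.zeros(dim)
        v0[int(np.argmin(diag))] = 1.0
        op = scipy.sparse.linalg.LinearOperator((dim, dim), matvec=sigma)
        try:
            evals, evecs = scipy.sparse.linalg.eigsh(
                op, k=max(nroots, 2), which="SA", v0=v0, maxiter=2000
            )
        except scipy.sparse.linalg.ArpackNoConvergence as exc:
            raise SolverError(f"FCI Lanczos did not converge: {exc}") from exc
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    roots = []
    for r in range(nroots):
        vec = evecs[:, r]
        # deterministic global phase: largest amplitude positive
        k = int(np.argmax(np.abs(vec)))
        if vec[k] < 0:
            vec = -vec
        roots.append(
            CIWavefunction(
                norb=norb,
                nelec=(na, nb),
                ci=vec.reshape(num_a, num_b).copy(),
                energy=float(evals[r] + ecore),
            )
        )
    return roots
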