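"""Dense second-quantization helpers for small numbers of fermionic modes.

Conventions (fixed package-wide):

* Spin orbitals are ordered site-ascending with up before down, i.e. the
  mode sequence for spatial orbitals ``0, 1, ...`` is
  ``(0, up), (0, dn), (1, up), (1, dn), ...``.
* A basis determinant ``|n_0 n_1 ... n_{m-1}>`` is built by applying the
  creation operators in mode order, ``(c0^+)^{n_0} (c1^+)^{n_1} ... |vac>``.
* Mode 0 is the slowest (most significant) index of the dense vector, so the
  left factor of a tensor product comes first.
* The four single-orbital Fock states are labelled ``|0>, |up>, |dn>, |updn>``
  (indices 0..3); in terms of the two spin-mode occupations ``(n_up, n_dn)``
  the label index is ``n_up + 2 n_dn``.

These dense objects are only ever used for <= ~16 modes (vectors of length
2^16); production RDM construction for large wavefunctions goes through the
string-based CI machinery instead.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "n_basis",
    "string_list",
    "occupations",
    "creation_operators",
    "number_operators",
    "mode_permutation_matrix",
    "partial_trace_vector",
    "partial_trace_matrix",
    "orbital_label_index",
    "two_orbital_reorder",
]

#: map (n_up, n_dn) -> index in the |0>,|up>,|dn>,|updn> single-orbital basis
_LABEL = {(0, 0): 0, (1, 0): 1, (0, 1): 2, (1, 1): 3}


def n_basis(n_modes: int) -> int:
    return 1 << n_modes


def string_list(norb: int, nelec: int) -> np.ndarray:
    """All occupation bitmasks with ``nelec`` of ``norb`` bits set, ascending.

    This fixes the determinant ordering shared by the CI solver and the
    CI-vector partial traces.
    """
    from itertools import combinations

    out = []
    for occ in combinations(range(norb), nelec):
        mask = 0
        for p in occ:
            mask |= 1 << p
        out.append(mask)
    out.sort()
    return np.array(out, dtype=np.int64)


def occupations(n_modes: int) -> np.ndarray:
    """(2^m, m) array of occupation numbers; mode 0 is the slowest index."""
    idx = np.arange(1 << n_modes)
    shifts = n_modes - 1 - np.arange(n_modes)
    return (idx[:, None] >> shifts[None, :]) & 1


@lru_cache(maxsize=32)
def creation_operators(n_modes: int) -> tuple[np.ndarray, ...]:
    """Jordan-Wigner creation matrices c_k^+ for all modes."""
    sp = np.array([[0.0, 0.0], [1.0, 0.0]])  # |1><0|
    z = np.diag([1.0, -1.0])
    eye = np.eye(2)
    ops = []
    for k in range(n_modes):
        mat = np.eye(1)
        for j in range(n_modes):
            if j < k:
                factor = z
            elif j == k:
                factor = sp
            else:
                factor = eye
            mat = np.kron(mat, factor)
        ops.append(mat)
    return tuple(ops)


def number_operators(n_modes: int) -> tuple[np.ndarray, ...]:
    cs = creation_operators(n_modes)
    return tuple(c @ c.T for c in cs)


def _perm_sign_on_occupied(perm: tuple[int, ...], occ: np.ndarray) -> int:
    """Sign of reordering creation operators from mode order to ``perm`` order.

    ``perm[j]`` is the original mode placed at new position ``j``.  Only the
    relative order of *occupied* modes matters.
    """
    seq = [p for p in perm if occ[p]]
    # parity of the permutation sorting `seq` ascending
    inv = 0
    for a in range(len(seq)):
        for b in range(a + 1, len(seq)):
            if seq[a] > seq[b]:
                inv += 1
    return -1 if inv & 1 else 1


def mode_permutation_matrix(perm, n_modes: int) -> np.ndarray:
    """Unitary implementing a relabelling of fermionic modes.

    Maps the state expressed in original mode order to the state expressed in
    the order ``perm`` (new position j holds original mode perm[j]), including
    the fermionic reordering signs.
    """
    perm = tuple(perm)
    if sorted(perm) != list(range(n_modes)):
        raise ValueError("perm must be a permutation of all modes")
    occ = occupations(n_modes)
    dim = 1 << n_modes
    shifts = n_modes - 1 - np.arange(n_modes)
    mat = np.zeros((dim, dim))
    for i in range(dim):
        new_occ = occ[i, list(perm)]
        j = int(np.sum(new_occ << shifts))
        mat[j, i] = _perm_sign_on_occupied(perm, occ[i])
    return mat


def partial_trace_vector(psi: np.ndarray, n_modes: int, keep) -> np.ndarray:
    """Reduced density matrix of modes ``keep`` (returned in that order)."""
    keep = list(keep)
    rest = [m for m in range(n_modes) if m not in keep]
    p = mode_permutation_matrix(keep + rest, n_modes)
    phi = (p @ psi).reshape(1 << len(keep), 1 << len(rest))
    return phi @ phi.conj().T


def partial_trace_matrix(rho: np.ndarray, n_modes: int, keep) -> np.ndarray:
    keep = list(keep)
    rest = [m for m in range(n_modes) if m not in keep]
    p = mode_permutation_matrix(keep + rest, n_modes)
    r = p @ rho @ p.conj().T
    dk, dr = 1 << len(keep), 1 << len(rest)
    r = r.reshape(dk, dr, dk, dr)
    return np.einsum("arbr->ab", r)


def orbital_label_index(n_up: int, n_dn: int) -> int:
    return _LABEL[(n_up, n_dn)]


def two_orbital_reorder() -> np.ndarray:
    """Permutation matrix from the 4-spin-mode JW basis of one orbital pair
    (modes i_up, i_dn, j_up, j_dn) to the published 16-dimensional basis
    ``|s_i> x |s_j>`` with s in (|0>,|up>,|dn>,|updn>).  Pure relabelling --
    the operator ordering conventions coincide, so no signs appear.
    """
    occ = occupations(4)
    mat = np.zeros((16, 16))
    for i in range(16):
        si = _LABEL[(occ[i, 0], occ[i, 1])]
        sj = _LABEL[(occ[i, 2], occ[i, 3])]
        mat[4 * si + sj, i] = 1.0
    return mat
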