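"""Independent brute-force second-quantization oracle for tests.

Implemented by explicit enumeration of occupation tuples (not by Kronecker
products), so it provides an independent check of the package's Fock-space
conventions: mode 0 is the most significant index and a determinant applies
creation operators in mode order.
"""

from itertools import product

import numpy as np


def basis_states(n_modes):
    return list(product((0, 1), repeat=n_modes))


def creation_matrix(n_modes: int, k: int) -> np.ndarray:
    states = basis_states(n_modes)
    index = {s: i for i, s in enumerate(states)}
    m = np.zeros((2**n_modes, 2**n_modes))
    for s in states:
        if s[k] == 1:
            continue
        t = list(s)
        t[k] = 1
        sign = (-1.0) ** sum(s[:k])
        m[index[tuple(t)], index[s]] = sign
    return m


def determinant_vector(n_modes: int, create_order: list[int]) -> np.ndarray:
    """|det> = c+_{o1} c+_{o2} ... |vac> applying the rightmost operator
    first."""
    v = np.zeros(2**n_modes)
    v[0] = 1.0
    for k in reversed(create_order):
        v = creation_matrix(n_modes, k) @ v
    return v


def ci_to_dense(ci: np.ndarray, norb: int, nelec) -> np.ndarray:
    """Dense vector of a CI wavefunction using the package's determinant
    convention: alpha creation operators (ascending) then beta (ascending),
    with spin-orbital modes ordered (site ascending, up before down)."""
    from meaobond.fockspace import string_list

    na, nb = nelec
    stra = string_list(norb, na)
    strb = string_list(norb, nb)
    n_modes = 2 * norb
    psi = np.zeros(2**n_modes)
    for ia, sa in enumerate(stra):
        for ib, sb in enumerate(strb):
            order = [2 * p for p in range(norb) if (int(sa) >> p) & 1]
            order += [2 * p + 1 for p in range(norb) if (int(sb) >> p) & 1]
            psi += ci[ia, ib] * determinant_vector(n_modes, order)
    return psi


def dense_partial_trace(psi: np.ndarray, n_modes: int, keep: list[int]) -> np.ndarray:
    """Reduced density matrix over ``keep`` (in that order), by explicitly
    re-expanding the state in a reordered operator basis."""
    rest = [m for m in range(n_modes) if m not in keep]
    order = keep + rest
    states = basis_states(n_modes)
    dk, dr = 2 ** len(keep), 2 ** len(rest)
    m = np.zeros((dk, dr))
    for s, amp in zip(states, psi):
        if amp == 0.0:
            continue
        occupied = [k for k in range(n_modes) if s[k]]
        # reorder creation operators into (keep | rest) order, counting sign
        target = [k for k in order if k in occupied]
        sign = 1
        seq = list(occupied)
        for t in target:
            pos = seq.index(t)
            sign *= (-1) ** pos
            seq.pop(pos)
        row = 0
        for k in keep:
            row = (row << 1) | s[k]
        col = 0
        for k in rest:
            col = (col << 1) | s[k]
        m[row, col] += sign * amp
    return m @ m.T


def entropy(rho: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(rho)
    ev = ev[ev > 1e-14]
    return float(-np.sum(ev * np.log(ev)))
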