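"""One- and two-orbital reduced density matrices, entropies and mutual
information.

Reduced states are produced through two routes:

* **CI route** — for string-based CI wavefunctions (objects exposing ``ci``,
  ``norb`` and ``nelec``), the reduced state of a small orbital subset is the
  exact partial trace of the CI vector, with fermionic reordering signs
  tracked explicitly.
* **Gaussian route** — for single-determinant (mean-field) states, reduced
  states are fermionic Gaussian states fully determined by the corresponding
  block of the one-particle RDM.

Mixed ensembles (objects exposing ``components`` as ``[(weight, state), ...]``)
reduce to the weighted average of their members' reduced states.

All 16x16 two-orbital RDMs are returned in the published product basis
``|0>,|up>,|dn>,|updn>`` per orbital, left orbital first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fockspace import occupations, string_list, two_orbital_reorder

__all__ = [
    "OneOrbitalRDM",
    "TwoOrbitalRDM",
    "von_neumann_entropy",
    "one_orbital_rdm",
    "two_orbital_rdm",
    "mutual_information",
    "ci_subset_rdm",
    "ci_bipartition_entropy",
]

_EIG_CLIP = 1e-14


def _sector_labels(n_orbitals: int) -> tuple[np.ndarray, np.ndarray]:
    """(N, 2*Sz) per basis index of the published n-orbital product basis."""
    n_per = np.array([0, 1, 1, 2])  # |0>,|up>,|dn>,|updn>
    sz2_per = np.array([0, 1, -1, 0])
    n = np.zeros(4**n_orbitals, dtype=int)
    sz2 = np.zeros(4**n_orbitals, dtype=int)
    for idx in range(4**n_orbitals):
        rem = idx
        for _ in range(n_orbitals):
            s = rem % 4
            n[idx] += n_per[s]
            sz2[idx] += sz2_per[s]
            rem //= 4
    return n, sz2


@dataclass
class OneOrbitalRDM:
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (4, 4):
            raise ValueError("one-orbital RDM must be 4x4")
        self.matrix = m

    @property
    def occupation_probabilities(self) -> np.ndarray:
        return np.real(np.diag(self.matrix))

    def entropy(self) -> float:
        return von_neumann_entropy(self.matrix)


@dataclass
class TwoOrbitalRDM:
    matrix: np.ndarray
    sector_n: np.ndarray = field(default=None)
    sector_sz2: np.ndarray = field(default=None)

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (16, 16):
            raise ValueError("two-orbital RDM must be 16x16")
        self.matrix = m
        if self.sector_n is None:
            self.sector_n, self.sector_sz2 = _sector_labels(2)

    def entropy(self) -> float:
        return von_neumann_entropy(self.matrix)

    def partial_trace(self, which: int) -> OneOrbitalRDM:
        """Trace out one orbital; ``which=0`` keeps the left orbital."""
        r = self.matrix.reshape(4, 4, 4, 4)
        if which == 0:
            return OneOrbitalRDM(np.einsum("asbs->ab", r))
        if which == 1:
            return OneOrbitalRDM(np.einsum("sasb->ab", r))
        raise ValueError("which must be 0 or 1")

    def off_sector_norm(self) -> float:
        """Largest magnitude outside the (N, Sz) superselection blocks."""
        same = (self.sector_n[:, None] == self.sector_n[None, :]) & (
            self.sector_sz2[:, None] == self.sector_sz2[None, :]
        )
        off = np.where(same, 0.0, np.abs(self.matrix))
        return float(off.max())


def von_neumann_entropy(rho: np.ndarray) -> float:
    """S(rho) = -Tr[rho log rho] in nats; eigenvalues below 1e-14 are zeros."""
    rho = np.asarray(rho)
    herm = 0.5 * (rho + rho.conj().T)
    if np.abs(rho - herm).max() > 1e-8:
        raise ValueError("density matrix is not hermitian")
    evals = np.linalg.eigvalsh(herm)
    if evals.min() < -1e-8:
        raise ValueError(f"density matrix has negative eigenvalue {evals.min():.3e}")
    evals = np.clip(evals, 0.0, None)
    ev = evals[evals > _EIG_CLIP]
    return float(-np.sum(ev * np.log(ev)))


# ---------------------------------------------------------------------------
# CI-vector partial traces
# ---------------------------------------------------------------------------


def _subset_sign_and_key(stra: int, strb: int, subset: list[int], norb: int):
    """Extract the spin modes of ``subset`` orbitals to the front.

    The determinant operator order is all alpha creation operators (orbital
    ascending) followed by all beta ones.  The target front order is
    ``p_up, p_dn`` for each p in ``subset`` (in the given subset order); the
    remaining (environment) operators keep their relative order.

    Returns (sign, row_index, env_key): ``row_index`` enumerates the subset
    spin-mode occupations with mode 0 as the most significant bit.
    """
    na = bin(stra).count("1")
    # positions of every operator in the original sequence
    seq = []  # (kind, orbital) in operator order
    removed = []
    sign = 1
    # original position of alpha op on orbital p: rank of p among set bits
    # of stra; beta op: na + rank among strb.
    front = []
    for p in subset:
        if (stra >> p) & 1:
            front.append(("a", p))
        if (strb >> p) & 1:
            front.append(("b", p))
    for kind, p in front:
        if kind == "a":
            pos = bin(stra & ((1 << p) - 1)).count("1")
        else:
            pos = na + bin(strb & ((1 << p) - 1)).count("1")
        # adjust for previously removed operators located before this one
        adj = sum(1 for rp in removed if rp < pos)
        pos -= adj
        # moving past `len(removed)` already-extracted front operators costs
        # nothing (they sit before position 0 of the remaining list)
        sign *= -1 if (pos % 2) else 1
        if kind == "a":
            removed.append(bin(stra & ((1 << p) - 1)).count("1"))
        else:
            removed.append(na + bin(strb & ((1 << p) - 1)).count("1"))
    row = 0
    for p in subset:
        row = (row << 1) | ((stra >> p) & 1)
        row = (row << 1) | ((strb >> p) & 1)
    sub_mask = 0
    for p in subset:
        sub_mask |= 1 << p
    env = (stra & ~sub_mask, strb & ~sub_mask)
    return sign, row, env


def _ci_amplitude_matrix(ci: np.ndarray, norb: int, nelec, subset) -> np.ndarray:
    """Amplitude matrix M[subset-config, environment-config] of a CI vector.

    Rows are indexed by the spin-mode occupations of ``subset`` in JW order
    (p_up, p_dn per orbital, mode 0 most significant); M @ M.T is the reduced
    density matrix of the subset in that basis.
    """
    na, nb = nelec
    stra = string_list(norb, na)
    strb = string_list(norb, nb)
    ci = np.asarray(ci).reshape(len(stra), len(strb))
    subset = list(subset)
    nrow = 4 ** len(subset)
    env_index: dict = {}
    rows_a = []
    # precompute per alpha string and per beta string independently?  The
    # sign couples alpha and beta occupations, so loop over determinants.
    cols = []
    data_rows = []
    signs = []
    for ia, sa in enumerate(stra):
        for ib, sb in enumerate(strb):
            amp = ci[ia, ib]
            if amp == 0.0:
                continue
            sign, row, env = _subset_sign_and_key(int(sa), int(sb), subset, norb)
            col = env_index.setdefault(env, len(env_index))
            cols.append(col)
            data_rows.append(row)
            signs.append(sign * amp)
    m = np.zeros((nrow, len(env_index)))
    for row, col, val in zip(data_rows, cols, signs):
        m[row, col] += val
    return m


def ci_subset_rdm(ci: np.ndarray, norb: int, nelec, subset) -> np.ndarray:
    """Exact reduced density matrix of an orbital subset of a CI wavefunction,
    in the JW spin-mode basis (p_up, p_dn per subset orbital)."""
    m = _ci_amplitude_matrix(ci, norb, nelec, subset)
    return m @ m.T


def ci_bipartition_entropy(ci: np.ndarray, norb: int, nelec, subset) -> float:
    """Entanglement entropy of the bipartition (subset | rest) of a pure CI
    wavefunction, in nats."""
    m = _ci_amplitude_matrix(ci, norb, nelec, subset)
    sv = np.linalg.svd(m, compute_uv=False)
    p = sv**2
    p = p[p > _EIG_CLIP]
    p = p / p.sum()
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# Gaussian (single determinant / mean field) route
# ---------------------------------------------------------------------------


def _gaussian_two_mode_rdm(d: np.ndarray) -> np.ndarray:
    """4x4 RDM of two spinless modes of a Gaussian (determinantal) state with
    one-particle density block ``d`` (2x2, d[p,q] = <c_q^+ c_p>), in the JW
    basis ordered |00>,|01>,|10>,|11> (first mode = most significant bit)."""
    d = 0.5 * (d + d.T)
    nu, v = np.linalg.eigh(d)
    nu = np.clip(nu, 0.0, 1.0)
    diag = np.array(
        [
            (1 - nu[0]) * (1 - nu[1]),
            (1 - nu[0]) * nu[1],
            nu[0] * (1 - nu[1]),
            nu[0] * nu[1],
        ]
    )
    r = np.zeros((4, 4))
    r[0, 0] = 1.0
    r[3, 3] = np.linalg.det(v)
    # N=1 sector: |10> (first mode) has JW index 2, |01> index 1
    r[np.ix_([2, 1], [2, 1])] = v
    return r @ np.diag(diag) @ r.T


def _mean_field_two_orbital(gamma: np.ndarray, i: int, j: int) -> np.ndarray:
    """16x16 two-orbital RDM of a closed-shell determinant with spin-summed
    1RDM ``gamma`` in the analysis basis, in the published basis."""
    from .fockspace import mode_permutation_matrix

    d = 0.5 * gamma[np.ix_([i, j], [i, j])]
    rho_spin = _gaussian_two_mode_rdm(d)
    rho = np.kron(rho_spin, rho_spin)  # modes (i_up, j_up, i_dn, j_dn)
    perm = mode_permutation_matrix((0, 2, 1, 3), 4)  # -> (i_up, i_dn, j_up, j_dn)
    rho = perm @ rho @ perm.T
    reorder = two_orbital_reorder()
    return reorder @ rho @ reorder.T


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def _norb_of(solution) -> int:
    if hasattr(solution, "norb"):
        return solution.norb
    if hasattr(solution, "gamma"):
        return np.asarray(solution.gamma).shape[0]
    raise TypeError("cannot infer orbital count from solution")


def two_orbital_rdm(solution, i: int, j: int) -> TwoOrbitalRDM:
    """Reduced state of orbitals (i, j) of a correlated, mean-field or
    ensemble solution, in the published 16-dimensional basis."""
    if i == j:
        raise ValueError("orbital indices must differ")
    n = _norb_of(solution)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"orbital index out of range for {n} orbitals")
    if hasattr(solution, "components"):
        mat = np.zeros((16, 16))
        for w, member in solution.components:
            mat += w * two_orbital_rdm(member, i, j).matrix
        return TwoOrbitalRDM(mat)
    if hasattr(solution, "ci"):
        rho_jw = ci_subset_rdm(solution.ci, solution.norb, solution.nelec, [i, j])
        reorder = two_orbital_reorder()
        return TwoOrbitalRDM(reorder @ rho_jw @ reorder.T)
    if hasattr(solution, "gamma"):
        return TwoOrbitalRDM(_mean_field_two_orbital(np.asarray(solution.gamma), i, j))
    raise TypeError(f"unsupported solution object {type(solution)!r}")


def one_orbital_rdm(solution, i: int) -> OneOrbitalRDM:
    n = _norb_of(solution)
    if not (0 <= i < n):
        raise IndexError(f"orbital index out of range for {n} orbitals")
    if hasattr(solution, "components"):
        mat = np.zeros((4, 4))
        for w, member in solution.components:
            mat += w * one_orbital_rdm(member, i).matrix
        return OneOrbitalRDM(mat)
    if hasattr(solution, "ci"):
        rho_jw = ci_subset_rdm(solution.ci, solution.norb, solution.nelec, [i])
        # JW order |00>,|01>,|10>,|11> = |0>,|dn>,|up>,|updn>
        perm = np.array([0, 2, 1, 3])
        return OneOrbitalRDM(rho_jw[np.ix_(perm, perm)])
    if hasattr(solution, "gamma"):
        g = np.asarray(solution.gamma)
        u = v = 0.5 * float(np.real(g[i, i]))
        diag = [(1 - u) * (1 - v), u * (1 - v), (1 - u) * v, u * v]
        return OneOrbitalRDM(np.diag(diag))
    raise TypeError(f"unsupported solution object {type(solution)!r}")


def mutual_information(solution, i: int, j: int) -> float:
    """I_ij = S(rho_i) + S(rho_j) - S(rho_ij), in nats."""
    rho_ij = two_orbital_rdm(solution, i, j)
    si = rho_ij.partial_trace(0).entropy()
    sj = rho_ij.partial_trace(1).entropy()
    return max(0.0, si + sj - rho_ij.entropy())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_rdms_hdf5(path, rdms: dict):
    """Write a mapping {name: TwoOrbitalRDM | OneOrbitalRDM} to HDF5, with
    superselection block labels attached to two-orbital entries."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, rdm in rdms.items():
            g = f.create_group(str(name))
            g.create_dataset("matrix", data=np.asarray(rdm.matrix))
            if isinstance(rdm, TwoOrbitalRDM):
                g.create_dataset("sector_n", data=rdm.sector_n)
                g.create_dataset("sector_sz2", data=rdm.sector_sz2)


def load_rdms_hdf5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            m = g["matrix"][...]
            if m.shape == (16, 16):
                out[name] = TwoOrbitalRDM(
                    m, g["sector_n"][...], g["sector_sz2"][...]
                )
            else:
                out[name] = OneOrbitalRDM(m)
    return out
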