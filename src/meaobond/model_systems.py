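"""Closed-form model states used as analytic fixtures.

Everything here is exact and engine-free: the idealized two-orbital covalent
bond state, symmetrically orthogonalized orbital pairs for a given overlap,
GHZ/W qubit registers, and a synthetic covalent-to-ionic interpolation family.
All amplitudes follow the package-wide conventions of :mod:`meaobond.fockspace`
(two-orbital Fock basis ``|0>,|up>,|dn>,|updn>`` per orbital, left factor
first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoOrbitalState",
    "QubitRegisterState",
    "symmetric_orthogonalization",
    "bond_state",
    "ghz_state",
    "w_state",
    "ionicity_family",
]

LOG4 = float(np.log(4.0))

# indices in the 16-dim basis 4*s_left + s_right, s in (0, up, dn, updn)
_IDX_0_UPDN = 3
_IDX_UP_DN = 6
_IDX_DN_UP = 9
_IDX_UPDN_0 = 12


@dataclass(frozen=True)
class TwoOrbitalState:
    """Pure state of two orbitals in the 16-dimensional product Fock basis."""

    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=complex)
        if c.shape != (16,):
            raise ValueError("two-orbital state needs 16 amplitudes")
        object.__setattr__(self, "coefficients", c)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.coefficients))

    def density_matrix(self) -> np.ndarray:
        c = self.coefficients
        return np.outer(c, c.conj())


@dataclass(frozen=True)
class QubitRegisterState:
    """Pure state of K two-level systems (amplitude vector of length 2^K)."""

    amplitudes: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=complex)
        k = int(np.log2(a.size))
        if 1 << k != a.size:
            raise ValueError("amplitude count must be a power of two")
        object.__setattr__(self, "amplitudes", a)

    @property
    def n_qubits(self) -> int:
        return int(np.log2(self.amplitudes.size))


def symmetric_orthogonalization(overlap: float) -> tuple[float, float]:
    """Coefficients (a, b) of the symmetrically orthogonalized left orbital,
    ``phi~_L = a phi_L + b phi_R``, for two normalized orbitals with overlap S.

    By symmetry ``phi~_R = b phi_L + a phi_R``.  The pair is orthonormal under
    the metric [[1, S], [S, 1]].
    """
    s = float(overlap)
    if not (0.0 <= s < 1.0):
        raise ValueError(f"overlap must lie in [0, 1), got {s}")
    a = 0.5 * (1.0 / np.sqrt(1.0 + s) + 1.0 / np.sqrt(1.0 - s))
    b = 0.5 * (1.0 / np.sqrt(1.0 + s) - 1.0 / np.sqrt(1.0 - s))
    return float(a), float(b)


def bond_state() -> TwoOrbitalState:
    """The idealized single covalent bond between two orthogonal atomic
    orbitals: an electron pair in the bonding orbital, re-expressed in the
    symmetrically orthogonalized local basis.  Maximally entangled (E = log 4).
    """
    c = np.zeros(16)
    c[_IDX_0_UPDN] = 0.5
    c[_IDX_UP_DN] = 0.5
    c[_IDX_DN_UP] = -0.5
    c[_IDX_UPDN_0] = 0.5
    return TwoOrbitalState(c)


def ghz_state(n_qubits: int = 3) -> QubitRegisterState:
    if n_qubits < 3:
        raise ValueError("GHZ register needs at least 3 qubits")
    amp = np.zeros(1 << n_qubits)
    amp[0] = amp[-1] = 1.0 / np.sqrt(2.0)
    return QubitRegisterState(amp)


def w_state(n_qubits: int = 3) -> QubitRegisterState:
    if n_qubits < 3:
        raise ValueError("W register needs at least 3 qubits")
    amp = np.zeros(1 << n_qubits)
    for k in range(n_qubits):
        amp[1 << k] = 1.0 / np.sqrt(n_qubits)
    return QubitRegisterState(amp)


def ionicity_family(mixing: float) -> TwoOrbitalState:
    """Normalized interpolation between the covalent bond state (mixing=0) and
    the fully ionic product state ``|updn, 0>`` (mixing=1).

    Synthetic family for monotonicity checks; not a fit to any molecule.
    """
    lam = float(mixing)
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"mixing must lie in [0, 1], got {lam}")
    c = (1.0 - lam) * bond_state().coefficients.real.copy()
    c[_IDX_UPDN_0] += lam
    c /= np.linalg.norm(c)
    return TwoOrbitalState(c)
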