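"""Adapter to the electronic-structure engine.

All module boundaries pass plain arrays (MO coefficients, overlap metrics,
RDM elements), so any engine able to provide mean-field solutions and CI
wavefunctions can back this interface.  The reference implementation uses
the bundled :mod:`meaobond.engine` (density-fitted RHF + determinant FCI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Molecule, RHF, read_xyz
from .engine.ci import CIWavefunction, SolverError, solve_fci

__all__ = [
    "MeanFieldResult",
    "CorrelatedSolution",
    "OrbitalDeterminantState",
    "ThermalEnsemble",
    "CapabilityError",
    "run_mean_field",
    "solve_cas",
    "thermal_ensemble",
    "DEFAULT_BETA",
]

#: inverse temperature (hartree^-1) used for low-temperature thermal states
DEFAULT_BETA = 1.0e3


class CapabilityError(NotImplementedError):
    """Requested feature is outside the bundled engine's capabilities."""


@dataclass
class MeanFieldResult:
    """Converged mean-field solution (plain arrays over the AO basis)."""

    mol: Molecule
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    mo_occ: np.ndarray
    s: np.ndarray  # AO overlap metric
    energy: float
    n_electrons: int
    method: str
    engine: RHF = field(repr=False, default=None)

    @property
    def gamma_ao(self) -> np.ndarray:
        """Spin-free 1RDM over the AO basis (Tr[gamma S] = N)."""
        occ = self.mo_occ > 0
        return (self.mo_coeff[:, occ] * self.mo_occ[occ]) @ self.mo_coeff[:, occ].T

    def gamma_in(self, coeffs: np.ndarray) -> np.ndarray:
        """Spin-free 1RDM expressed in an orthonormal orbital basis given by
        AO coefficient columns."""
        sc = self.s @ coeffs
        return sc.T @ self.gamma_ao @ sc

    def orbital_state(self, coeffs: np.ndarray) -> "OrbitalDeterminantState":
        """The determinant viewed as a state of the orbitals ``coeffs``."""
        return OrbitalDeterminantState(self.gamma_in(coeffs))


@dataclass
class OrbitalDeterminantState:
    """Closed-shell determinant restricted to an orthonormal orbital set;
    reduced states follow from ``gamma`` alone (fermionic Gaussian state)."""

    gamma: np.ndarray

    @property
    def norb(self) -> int:
        return self.gamma.shape[0]


@dataclass
class CorrelatedSolution:
    """CI solution over an orthonormal active orbital basis.

    Exposes ``ci``, ``norb``, ``nelec`` for the RDM machinery, plus
    accessors for the spin-free 1RDM and the opposite-spin 2RDM block.
    """

    wavefunction: CIWavefunction
    orbital_coefficients: np.ndarray  # AO coefficients of the active orbitals
    energy: float
    closed_coefficients: np.ndarray = None
    e_core: float = 0.0

    @property
    def ci(self) -> np.ndarray:
        return self.wavefunction.ci

    @property
    def norb(self) -> int:
        return self.wavefunction.norb

    @property
    def nelec(self) -> tuple[int, int]:
        return self.wavefunction.nelec

    def gamma(self) -> np.ndarray:
        return self.wavefunction.gamma()

    @property
    def gab(self) -> np.ndarray:
        return self.wavefunction.rdm2_ab()


@dataclass
class ThermalEnsemble:
    """Boltzmann mixture of eigenstates at inverse temperature beta."""

    members: list
    energies: np.ndarray
    beta: float
    weights: np.ndarray

    @property
    def components(self):
        return list(zip(self.weights, self.members))

    @property
    def norb(self) -> int:
        return self.members[0].norb

    @property
    def gab(self) -> np.ndarray:
        """Thermal opposite-spin 2RDM = weighted average of member 2RDMs."""
        out = None
        for w, m in self.components:
            g = m.gab
            out = w * g if out is None else out + w * g
        return out

    def gamma(self) -> np.ndarray:
        out = None
        for w, m in self.components:
            g = m.gamma()
            out = w * g if out is None else out + w * g
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def run_mean_field(
    geometry,
    basis: str,
    method: str = "hf",
    charge: int = 0,
    auxbasis: str = "def2-universal-jkfit",
    conv_tol: float = 1e-9,
) -> MeanFieldResult:
    """Converged closed-shell mean field for an XYZ geometry (path, literal
    string, or atom list)."""
    if method.lower() not in ("hf", "rhf"):
        raise CapabilityError(
            f"mean-field method {method!r} is not available in the bundled "
            "engine (restricted Hartree-Fock only); density-functional "
            "references require an external engine behind this adapter"
        )
    mol = geometry if isinstance(geometry, Molecule) else Molecule(geometry, basis, charge)
    if mol.basis_name != basis.strip().lower() and basis:
        mol = mol.with_basis(basis)
    mf = RHF(mol, auxbasis=auxbasis, conv_tol=conv_tol)
    energy = mf.kernel()
    res = MeanFieldResult(
        mol=mol,
        mo_coeff=mf.mo_coeff,
        mo_energy=mf.mo_energy,
        mo_occ=mf.mo_occ,
        s=mf.s,
        energy=energy,
        n_electrons=mol.nelectron,
        method="hf",
        engine=mf,
    )
    return res


def solve_cas(
    mf: MeanFieldResult,
    active_coeffs: np.ndarray,
    n_active_electrons: int,
    closed_coeffs: np.ndarray = None,
    solver: str = "fci",
    nroots: int = 1,
    nelec_spin: tuple[int, int] = None,
):
    """CAS/full-CI over an orthonormal active orbital set with optional
    doubly-occupied closed orbitals.

    Returns a single :class:`CorrelatedSolution` (or a list when
    ``nroots > 1``).
    """
    solver = solver.lower()
    if solver == "dmrg":
        raise CapabilityError(
            "the bundled engine has no DMRG solver; active spaces here are "
            "small enough for exact FCI (use solver='fci')"
        )
    if solver != "fci":
        raise ValueError(f"unknown solver {solver!r}")
    norb = active_coeffs.shape[1]
    if nelec_spin is None:
        if n_active_electrons % 2:
            raise ValueError(
                "odd active electron count requires explicit nelec_spin"
            )
        nelec_spin = (n_active_electrons // 2, n_active_electrons // 2)
    if sum(nelec_spin) != n_active_electrons:
        raise ValueError("nelec_spin inconsistent with n_active_electrons")
    if n_active_electrons > 2 * norb:
        raise ValueError("too many electrons for the active space")
    if closed_coeffs is None:
        closed_coeffs = np.zeros((active_coeffs.shape[0], 0))
    # orthogonality sanity
    cross = closed_coeffs.T @ mf.s @ active_coeffs
    if cross.size and np.abs(cross).max() > 1e-8:
        raise ValueError("closed and active orbitals are not orthogonal")
    h_act, eri_act, e_core = mf.engine.active_space_hamiltonian(
        active_coeffs, closed_coeffs
    )
    roots = solve_fci(
        h_act, eri_act, norb, nelec_spin, nroots=nroots, ecore=e_core
    )
    sols = [
        CorrelatedSolution(
            wavefunction=r,
            orbital_coefficients=active_coeffs,
            energy=r.energy,
            closed_coefficients=closed_coeffs,
            e_core=e_core,
        )
        for r in roots
    ]
    return sols if nroots > 1 else sols[0]


def thermal_ensemble(states, energies, beta: float = DEFAULT_BETA) -> ThermalEnsemble:
    """Boltzmann-weighted ensemble of the given states."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if not states:
        raise ValueError("thermal ensemble needs at least one state")
    energies = np.asarray(energies, float)
    if len(energies) != len(states) or not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite and match the state count")
    x = -beta * (energies - energies.min())
    w = np.exp(x)
    w = w / w.sum()
    return ThermalEnsemble(list(states), energies, float(beta), w)
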