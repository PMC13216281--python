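"""Maximally entangled atomic orbitals: the inter-center coherence objective
and its maximization over partition-preserving orbital rotations.

The objective is the sum over inter-atom orbital pairs of the two squared
bond coherences of the opposite-spin 2RDM,

    F = sum_{i<j} |Gamma^{i up, i dn}_{j up, j dn}|^2
               + |Gamma^{i up, j dn}_{j up, i dn}|^2 .

Two 2RDM sources are supported:

* a closed-shell single determinant, supplied as the spin-summed 1RDM in the
  partition basis (both coherences then reduce to (D_ij/2)^2, so
  F = sum_{i<j} D_ij^4 / 8);
* a correlated or thermal opposite-spin 2RDM tensor
  ``gab[p,q,r,s] = <f+_p,up f+_q,dn f_s,dn f_r,up>`` in the partition basis.

The optimizer is a safeguarded diagonal-Hessian Newton ascent over per-atom
antisymmetric generators, with backtracking guaranteeing monotone increase,
and seeded random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .atomic_partition import AtomicPartition

__all__ = [
    "MeanFieldSource",
    "CoherenceTensorSource",
    "MEAOBasis",
    "f_meao",
    "f_meao_gradient",
    "optimize_meao",
    "inter_center_entanglement_sum",
]


@dataclass
class MeanFieldSource:
    """Closed-shell determinant 2RDM source: spin-summed 1RDM in the
    partition basis (trace = electron count)."""

    gamma: np.ndarray

    def rotated(self, u: np.ndarray) -> "MeanFieldSource":
        return MeanFieldSource(u.T @ self.gamma @ u)


@dataclass
class CoherenceTensorSource:
    """General 2RDM source: the opposite-spin block as a 4-index tensor."""

    gab: np.ndarray

    def rotated(self, u: np.ndarray) -> "CoherenceTensorSource":
        g = np.einsum("abcd,ap,bq,cr,ds->pqrs", self.gab, u, u, u, u, optimize=True)
        return CoherenceTensorSource(g)


def _as_source(source):
    if isinstance(source, (MeanFieldSource, CoherenceTensorSource)):
        return source
    if hasattr(source, "gab"):
        return CoherenceTensorSource(np.asarray(source.gab))
    if hasattr(source, "gamma"):
        g = source.gamma() if callable(source.gamma) else source.gamma
        return MeanFieldSource(np.asarray(g))
    raise TypeError(f"unsupported 2RDM source {type(source)!r}")


def _inter_mask(partition: AtomicPartition) -> np.ndarray:
    return partition.inter_center_mask().astype(float)


def f_meao(source, partition: AtomicPartition) -> float:
    """Evaluate the inter-center coherence objective in the partition basis."""
    src = _as_source(source)
    mask = _inter_mask(partition)
    n = partition.n_orbitals
    if isinstance(src, MeanFieldSource):
        if src.gamma.shape != (n, n):
            raise ValueError("1RDM dimension does not match the partition")
        return float(np.sum(mask * src.gamma**4) / 16.0)
    gab = src.gab
    if gab.shape != (n,) * 4:
        raise ValueError("2RDM dimension does not match the partition")
    c1 = np.einsum("iijj->ij", gab)
    c2 = np.einsum("ijji->ij", gab)
    return float(0.5 * np.sum(mask * (c1**2 + c2**2)))


# ---------------------------------------------------------------------------
# gradient over block-rotation generators
# ---------------------------------------------------------------------------


def _param_index(partition: AtomicPartition):
    """(p, q) orbital index pairs (p<q, same atom) parametrizing rotations."""
    pairs = []
    for block in partition.blocks():
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                pairs.append((int(block[a]), int(block[b])))
    return pairs


def _pack(x_full: np.ndarray, pairs) -> np.ndarray:
    return np.array([x_full[p, q] for p, q in pairs])


def _unpack(theta: np.ndarray, pairs, n: int) -> np.ndarray:
    x = np.zeros((n, n))
    for k, (p, q) in enumerate(pairs):
        x[p, q] = theta[k]
        x[q, p] = -theta[k]
    return x


def f_meao_gradient(source, partition: AtomicPartition) -> np.ndarray:
    """Analytic gradient of f_meao with respect to the per-atom antisymmetric
    generators, evaluated at zero rotation; returned as the full antisymmetric
    matrix (entries outside atom blocks are zero).

    Convention: for U -> U exp(X), quantities transform with exp(X) on every
    orbital index, and dF = sum_{p<q} grad[p, q] * X[p, q].
    """
    src = _as_source(source)
    mask = _inter_mask(partition)
    n = partition.n_orbitals
    block_mask = 1.0 - mask  # same-atom pairs
    if isinstance(src, MeanFieldSource):
        d = src.gamma
        g = 0.25 * mask * d**3  # dF/dD_ij over ordered pairs
        # dD = [D, X] under U -> U exp(X);  dF = Tr((D G - G D) X)
        w = d @ g - g @ d  # antisymmetric
        grad = 2.0 * w
    else:
        gab = src.gab
        c1 = np.einsum("iijj->ij", gab)
        c2 = np.einsum("ijji->ij", gab)
        z = np.zeros_like(gab)
        ii, jj = np.nonzero(mask)
        for i, j in zip(ii, jj):  # all ordered inter-center pairs
            z[i, i, j, j] += c1[i, j]
            z[i, j, j, i] += c2[i, j]
        # dGamma'[pqrs]/dX = sum over slots of X acting on that slot
        c_a = np.einsum("pqrs,aqrs->ap", z, gab, optimize=True)
        c_b = np.einsum("pqrs,pars->aq", z, gab, optimize=True)
        c_c = np.einsum("pqrs,pqas->ar", z, gab, optimize=True)
        c_d = np.einsum("pqrs,pqra->as", z, gab, optimize=True)
        c_tot = c_a + c_b + c_c + c_d  # dF = sum_{ap} c_tot[a,p] X[a,p]
        grad = c_tot - c_tot.T
    grad = grad * block_mask
    np.fill_diagonal(grad, 0.0)
    return grad


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


@dataclass
class MEAOBasis:
    partition: AtomicPartition
    objective: float
    iteration_trace: list = field(default_factory=list)
    restart_index: int = 0
    seed: int = 0
    converged: bool = True
    block_rotations: list = field(default_factory=list)


class MEAOConvergenceError(RuntimeError):
    def __init__(self, message, best: MEAOBasis):
        super().__init__(message)
        self.best = best


def _block_expm(x_full: np.ndarray, blocks) -> np.ndarray:
    u = np.eye(x_full.shape[0])
    for b in blocks:
        u[np.ix_(b, b)] = scipy.linalg.expm(x_full[np.ix_(b, b)])
    return u


def optimize_meao(
    source,
    partition: AtomicPartition,
    seed: int = 0,
    restarts: int = 4,
    gtol: float = 1e-8,
    max_iterations: int = 200,
    strict: bool = False,
) -> MEAOBasis:
    """Maximize f_meao over partition-preserving rotations.

    Deterministic given ``seed``: restart 0 starts from the identity, the
    others from seeded random block rotations.  The best restart wins; ties
    (< 1e-10) go to the lowest restart index.
    """
    src0 = _as_source(source)
    pairs = _param_index(partition)
    blocks = partition.blocks()
    n = partition.n_orbitals
    if not pairs:
        val = f_meao(src0, partition)
        return MEAOBasis(partition, val, [(0, val, 0.0, 0.0)], 0, seed, True,
                         [np.eye(len(b)) for b in blocks])

    best: MEAOBasis | None = None
    for restart in range(restarts):
        rng = np.random.default_rng((seed, restart))
        if restart == 0:
            theta0 = np.zeros(len(pairs))
        else:
            theta0 = 0.4 * rng.standard_normal(len(pairs))
        u_total = _block_expm(_unpack(theta0, pairs, n), blocks)
        src = src0.rotated(u_total)
        part = partition  # masks only depend on atom_of, unchanged by rotation
        val = f_meao(src, part)
        trace = [(0, val, np.nan, np.nan)]
        converged = False
        for it in range(1, max_iterations + 1):
            grad_full = f_meao_gradient(src, part)
            g = _pack(grad_full, pairs)
            gnorm = np.abs(g).max() if len(g) else 0.0
            if gnorm < gtol:
                converged = True
                trace.append((it, val, gnorm, 0.0))
                break
            # diagonal Hessian by central differences of the objective
            h = np.empty(len(pairs))
            eps = 1e-4
            for k in range(len(pairs)):
                e = np.zeros(len(pairs))
                e[k] = eps
                up = _block_expm(_unpack(e, pairs, n), blocks)
                um = _block_expm(_unpack(-e, pairs, n), blocks)
                fp = f_meao(src.rotated(up), part)
                fm = f_meao(src.rotated(um), part)
                h[k] = (fp - 2.0 * val + fm) / eps**2
            # ascent direction: Newton on the concave directions, Levenberg
            # shift where curvature is not negative
            denom = np.where(h < -1e-12, -h, np.abs(h) + 1e-2)
            d = g / denom
            # backtracking line search (monotone ascent)
            step = 1.0
            improved = False
            for _bt in range(40):
                u_step = _block_expm(_unpack(step * d, pairs, n), blocks)
                cand = src.rotated(u_step)
                f_new = f_meao(cand, part)
                if f_new > val:
                    src = cand
                    u_total = u_total @ u_step
                    step_norm = float(np.linalg.norm(step * d))
                    val = f_new
                    trace.append((it, val, gnorm, step_norm))
                    improved = True
                    break
                step *= 0.5
            if not improved:
                # stationary within numerical resolution
                converged = gnorm < 1e-5
                trace.append((it, val, gnorm, 0.0))
                break
        result = MEAOBasis(
            partition=partition.rotated(
                [u_total[np.ix_(b, b)] for b in blocks]
            ),
            objective=val,
            iteration_trace=trace,
            restart_index=restart,
            seed=seed,
            converged=converged,
            block_rotations=[u_total[np.ix_(b, b)] for b in blocks],
        )
        if best is None or result.objective > best.objective + 1e-10:
            best = result
    if strict and not best.converged:
        raise MEAOConvergenceError(
            "MEAO optimization did not reach the gradient tolerance", best
        )
    return best


def inter_center_entanglement_sum(solution, partition: AtomicPartition, **ree_kwargs) -> float:
    """Direct sum of pairwise relative entropies of entanglement over all
    inter-atom orbital pairs (diagnostic; feasible for small systems)."""
    from .entanglement import relative_entropy_of_entanglement
    from .fock_rdm import two_orbital_rdm

    n = partition.n_orbitals
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if partition.atom_of[i] == partition.atom_of[j]:
                continue
            rho = two_orbital_rdm(solution, i, j)
            total += relative_entropy_of_entanglement(rho.matrix, **ree_kwargs)
    return float(total)
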