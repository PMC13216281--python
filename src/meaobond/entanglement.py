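"""Entanglement measures: pure-state bipartite entropy, relative entropy of
entanglement for mixed two-orbital states, and genuine multipartite
entanglement (GME) of pure cluster states.

The relative entropy of entanglement

    E(rho) = min_{sigma in SEP} Tr[rho (log rho - log sigma)]

is computed by Frank-Wolfe over the convex set of separable states of the two
factors: at each iterate the linearized subproblem (the best pure product
state against the gradient) is solved by alternating power iteration, and an
exact line search updates the mixture.  The Frank-Wolfe gap upper-bounds the
remaining error, so the returned value is accurate to the gap tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fock_rdm import ci_bipartition_entropy, von_neumann_entropy
from .model_systems import QubitRegisterState, TwoOrbitalState

__all__ = [
    "SeparableApproximant",
    "GMEResult",
    "pure_bipartite_entanglement",
    "relative_entropy_of_entanglement",
    "gme",
]

_CLIP = 1e-14


@dataclass
class SeparableApproximant:
    """Best separable state found by the iterative minimization."""

    sigma: np.ndarray
    value: float
    gap: float
    n_iterations: int
    converged: bool
    trace: list = field(default_factory=list)


@dataclass
class GMEResult:
    value: float
    normalized: float
    minimizing_subset: tuple
    mode: str
    n_bipartitions: int


# ---------------------------------------------------------------------------
# pure states
# ---------------------------------------------------------------------------


def _state_vector(state) -> np.ndarray:
    if isinstance(state, TwoOrbitalState):
        return state.coefficients
    if isinstance(state, QubitRegisterState):
        return state.amplitudes
    if isinstance(state, np.ndarray) and state.ndim == 1:
        return state
    raise TypeError(
        "expected a pure state vector; for mixed states use "
        "relative_entropy_of_entanglement"
    )


def pure_bipartite_entanglement(state, dims: tuple[int, int], subsystem: int = 0) -> float:
    """Entanglement entropy S(rho_A) of a pure state split into factors of
    dimensions ``dims``; equals S(rho_B) by the Schmidt decomposition."""
    psi = _state_vector(state)
    da, db = dims
    if psi.size != da * db:
        raise ValueError("state dimension does not match the factor dimensions")
    m = psi.reshape(da, db)
    sv = np.linalg.svd(m, compute_uv=False)
    p = sv**2
    p = p[p > _CLIP]
    p = p / p.sum()
    s = float(-np.sum(p * np.log(p)))
    return s if subsystem in (0, 1) else s


# ---------------------------------------------------------------------------
# relative entropy of entanglement
# ---------------------------------------------------------------------------


def _rel_entropy_terms(rho: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(rho)
    ev = ev[ev > _CLIP]
    return float(np.sum(ev * np.log(ev)))


def _objective(rho: np.ndarray, sigma: np.ndarray, tr_rho_log_rho: float) -> float:
    lam, u = np.linalg.eigh(sigma)
    lam = np.clip(lam, _CLIP, None)
    log_sigma = (u * np.log(lam)) @ u.conj().T
    return tr_rho_log_rho - float(np.real(np.trace(rho @ log_sigma)))


def _gradient(rho: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """G = -grad f(sigma) = D log(sigma)[rho] (positive semidefinite)."""
    lam, u = np.linalg.eigh(sigma)
    lam = np.clip(lam, _CLIP, None)
    rt = u.conj().T @ rho @ u
    ll = np.log(lam)
    denom = lam[:, None] - lam[None, :]
    phi = np.where(
        np.abs(denom) > 1e-12,
        (ll[:, None] - ll[None, :]) / np.where(np.abs(denom) > 1e-12, denom, 1.0),
        1.0 / lam[:, None],
    )
    g = u @ (rt * phi) @ u.conj().T
    return 0.5 * (g + g.conj().T)


def _factor_sectors(d: int, separable_set: str) -> list[list[int]]:
    if separable_set == "unrestricted" or d != 4:
        return [list(range(d))]
    if separable_set == "number-superselected":
        # orbital Fock space |0>,|up>,|dn>,|updn>: N = 0, 1, 1, 2
        return [[0], [1, 2], [3]]
    if separable_set == "sector-diagonal":
        return [[0], [1], [2], [3]]
    raise ValueError(f"unknown separable_set {separable_set!r}")


def _best_product_state(g, dims, sectors_a, sectors_b, rng):
    """Maximize <x (x) y|G|x (x) y> over product states whose factors live in
    single local sectors.  Alternating eigenvector updates per sector combo;
    G is hermitian PSD so the scheme is monotone."""
    da, db = dims
    g4 = g.reshape(da, db, da, db).transpose(0, 2, 1, 3).reshape(da * da, db * db)
    best_val, best_vec = -np.inf, None
    for sa in sectors_a:
        for sb in sectors_b:
            for _start in range(2 if (len(sa) > 1 and len(sb) > 1) else 1):
                y = rng.standard_normal(len(sb)) + 1j * rng.standard_normal(len(sb))
                y /= np.linalg.norm(y)
                yf = np.zeros(db, complex)
                val = -np.inf
                for _ in range(100):
                    yf[:] = 0.0
                    yf[sb] = y
                    ga = (g4 @ np.outer(yf.conj(), yf).ravel()).reshape(da, da)
                    ga = ga[np.ix_(sa, sa)]
                    w, v = np.linalg.eigh(0.5 * (ga + ga.conj().T))
                    x = v[:, -1]
                    xf = np.zeros(da, complex)
                    xf[sa] = x
                    gb = (np.outer(xf.conj(), xf).ravel() @ g4).reshape(db, db)
                    gb = gb[np.ix_(sb, sb)]
                    w, v = np.linalg.eigh(0.5 * (gb + gb.conj().T))
                    y = v[:, -1]
                    new = float(w[-1])
                    if new - val < 1e-14:
                        val = new
                        break
                    val = new
                if val > best_val:
                    xf = np.zeros(da, complex)
                    xf[sa] = x
                    yf = np.zeros(db, complex)
                    yf[sb] = y
                    best_val, best_vec = val, np.kron(xf, yf)
    return best_vec, best_val


def _optimize_weights(rho, vecs, w0, tr_rr, n_steps=120):
    """Fully-corrective step: minimize f(sum_k w_k |v_k><v_k|) over the
    probability simplex by entropic mirror descent (monotone via halving)."""
    vmat = np.stack(vecs, axis=1)  # (dim, K)
    w = np.asarray(w0, float).copy()
    w = np.clip(w, 1e-15, None)
    w /= w.sum()

    def build(wv):
        return (vmat * wv) @ vmat.conj().T

    f_cur = _objective(rho, build(w), tr_rr)
    step = 1.0
    for _ in range(n_steps):
        g = _gradient(rho, build(w))  # -grad wrt sigma
        gk = np.real(np.einsum("ik,ij,jk->k", vmat.conj(), g, vmat))
        gk = gk - gk @ w  # center (gauge) for stability
        improved = False
        s = step
        for _try in range(25):
            wn = w * np.exp(s * gk)
            wn /= wn.sum()
            f_new = _objective(rho, build(wn), tr_rr)
            if f_new < f_cur - 1e-15:
                w, f_cur = wn, f_new
                step = min(s * 1.5, 1e3)
                improved = True
                break
            s *= 0.5
        if not improved:
            break
    return w, f_cur


def relative_entropy_of_entanglement(
    rho,
    dims: tuple[int, int] = (4, 4),
    separable_set: str = "number-superselected",
    tol: float = 1e-6,
    max_iterations: int = 300,
    seed: int = 0,
    return_approximant: bool = False,
):
    """Relative entropy of entanglement of a bipartite mixed state (nats).

    Parameters
    ----------
    rho : density matrix (or an object with a ``matrix`` attribute).
    dims : factor dimensions, default two orbital Fock spaces (4, 4).
    separable_set : which product states the separable mixtures are built
        from.  ``"number-superselected"`` (default) restricts each factor to
        a definite local particle number, which is the physically meaningful
        choice for fermionic orbital subsystems; ``"unrestricted"`` allows
        any product state; ``"sector-diagonal"`` additionally fixes local Sz
        (for 4-dimensional factors this reduces to diagonal states).

    The solver is fully-corrective Frank-Wolfe: the linearized subproblem
    adds the best product state to an explicit atom mixture, then the mixture
    weights are re-optimized; the Frank-Wolfe gap bounds the remaining error.
    """
    rho = np.asarray(getattr(rho, "matrix", rho), dtype=complex)
    da, db = dims
    if rho.shape != (da * db, da * db):
        raise ValueError("density matrix does not match the factor dimensions")
    rho = 0.5 * (rho + rho.conj().T)
    tr_rr = _rel_entropy_terms(rho)
    rng = np.random.default_rng(seed)
    sectors_a = _factor_sectors(da, separable_set)
    sectors_b = _factor_sectors(db, separable_set)

    # initial atoms: basis products weighted by the diagonal of rho (these
    # have definite local sectors, so they belong to every separable set)
    vecs = [
        np.kron(np.eye(da)[a], np.eye(db)[b]).astype(complex)
        for a in range(da)
        for b in range(db)
    ]
    weights = np.clip(np.real(np.diag(rho)), 1e-4, None)
    weights = weights / weights.sum()
    weights, value = _optimize_weights(rho, vecs, weights, tr_rr, n_steps=40)

    def build():
        vmat = np.stack(vecs, axis=1)
        return (vmat * weights) @ vmat.conj().T

    sigma = build()
    trace = []
    gap = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        g = _gradient(rho, sigma)
        vec, top = _best_product_state(g, dims, sectors_a, sectors_b, rng)
        tr_g_sigma = float(np.real(np.trace(g @ sigma)))
        gap = top - tr_g_sigma
        trace.append((value, gap))
        if gap < tol or value < 10 * tol:
            converged = True
            break
        vecs.append(vec)
        weights = np.concatenate([weights * (1 - 0.05), [0.05]])
        weights, value = _optimize_weights(rho, vecs, weights, tr_rr)
        # prune negligible atoms
        keep = weights > 1e-12
        if not keep.all():
            vecs = [v for v, k in zip(vecs, keep) if k]
            weights = weights[keep]
            weights /= weights.sum()
        sigma = build()
    value = max(0.0, value)
    if return_approximant:
        return value, SeparableApproximant(sigma, value, gap, it, converged, trace)
    return value


# ---------------------------------------------------------------------------
# genuine multipartite entanglement
# ---------------------------------------------------------------------------


def _subsets_exhaustive(k: int):
    """All bipartitions (A | complement) of k parties, A containing party 0."""
    from itertools import combinations

    for size in range(1, k):
        for rest in combinations(range(1, k), size - 1):
            a = (0,) + rest
            if len(a) < k:
                yield a


def _subsets_mps_cuts(k: int):
    """Single parties, pairs, and contiguous chain cuts."""
    seen = set()
    for i in range(k):
        seen.add((i,))
    for i in range(k):
        for j in range(i + 1, k):
            seen.add((i, j))
    for cut in range(1, k):
        seen.add(tuple(range(cut)))
    for s in sorted(seen, key=lambda s: (len(s), s)):
        if 0 < len(s) < k:
            yield s


def _qubit_subset_entropy(amp: np.ndarray, k: int, subset) -> float:
    t = amp.reshape((2,) * k)
    order = list(subset) + [q for q in range(k) if q not in subset]
    m = np.transpose(t, order).reshape(1 << len(subset), -1)
    sv = np.linalg.svd(m, compute_uv=False)
    p = sv**2
    p = p[p > _CLIP]
    return float(-np.sum(p * np.log(p)))


def gme(state, mode: str = "exhaustive") -> GMEResult:
    """Genuine multipartite entanglement of a pure state.

    ``state`` is either a :class:`QubitRegisterState` (parties are qubits) or
    a CI wavefunction object with ``ci``, ``norb``, ``nelec`` (parties are the
    orbitals of its active space).  Mixed states are not supported.
    """
    if mode not in ("exhaustive", "mps-cuts"):
        raise ValueError("mode must be 'exhaustive' or 'mps-cuts'")
    if isinstance(state, QubitRegisterState):
        k = state.n_qubits
        local_dim = 2
        entropy = lambda subset: _qubit_subset_entropy(state.amplitudes, k, subset)
    elif hasattr(state, "ci"):
        k = state.norb
        local_dim = 4
        entropy = lambda subset: ci_bipartition_entropy(
            state.ci, state.norb, state.nelec, subset
        )
    elif isinstance(state, np.ndarray) and state.ndim == 2:
        raise TypeError("GME of mixed states is not supported (pure states only)")
    else:
        raise TypeError(f"unsupported state object {type(state)!r}")
    if k < 2:
        raise ValueError("GME needs at least 2 parties")
    subsets = _subsets_exhaustive(k) if mode == "exhaustive" else _subsets_mps_cuts(k)
    best, best_subset, count = np.inf, None, 0
    for subset in subsets:
        count += 1
        s = entropy(subset)
        if s < best:
            best, best_subset = s, tuple(subset)
    value = max(0.0, float(best))
    return GMEResult(
        value=value,
        normalized=value / np.log(local_dim),
        minimizing_subset=best_subset,
        mode=mode,
        n_bipartitions=count,
    )
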