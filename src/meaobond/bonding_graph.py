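"""Orbital correlation graphs, bond clustering, and active-space construction.

Vertices are localized orbitals (with atom labels and single-orbital
entropies); edges carry the mutual information of inter-center pairs.  Pairs
whose correlation exceeds eta * I_max (default eta = 0.10, I_max = 2 log 4)
are connected; connected components with >= 2 vertices are bond clusters.
The active space of a multicenter cluster is completed by classifying the
natural orbitals of the non-active 1RDM as closed (occupation > 1) or
virtual (occupation < 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .fock_rdm import mutual_information, one_orbital_rdm

__all__ = [
    "CorrelationGraph",
    "BondCluster",
    "CASSpace",
    "I_MAX",
    "build_correlation_graph",
    "detect_bond_clusters",
    "build_cas_for_cluster",
    "best_subset_of_size",
]

I_MAX = 2.0 * np.log(4.0)
DEFAULT_ETA = 0.10


class AmbiguousOccupationError(RuntimeError):
    pass


@dataclass
class CorrelationGraph:
    graph: nx.Graph
    eta: float
    atom_of: np.ndarray
    entropies: np.ndarray
    mutual_info: np.ndarray  # full symmetric matrix (intra-atom kept for plots)

    @property
    def threshold(self) -> float:
        return self.eta * I_MAX

    def edges(self):
        return [
            (i, j, d["weight"]) for i, j, d in self.graph.edges(data=True)
        ]

    def isolated_orbitals(self) -> list[int]:
        return [v for v in self.graph.nodes if self.graph.degree(v) == 0]

    def to_dict(self) -> dict:
        return {
            "eta": self.eta,
            "i_max": I_MAX,
            "nodes": [
                {
                    "orbital": int(v),
                    "atom": int(self.atom_of[v]),
                    "entropy": float(self.entropies[v]),
                    "entropy_normalized": float(self.entropies[v] / np.log(4.0)),
                }
                for v in self.graph.nodes
            ],
            "edges": [
                {
                    "i": int(i),
                    "j": int(j),
                    "mutual_information": float(w),
                    "normalized": float(w / I_MAX),
                }
                for i, j, w in self.edges()
            ],
        }

    def to_graphml(self, path):
        g = nx.Graph()
        for v in self.graph.nodes:
            g.add_node(
                int(v),
                atom=int(self.atom_of[v]),
                entropy=float(self.entropies[v]),
            )
        for i, j, w in self.edges():
            g.add_edge(int(i), int(j), weight=float(w), normalized=float(w / I_MAX))
        nx.write_graphml(g, path)


@dataclass
class BondCluster:
    orbitals: tuple
    atoms: tuple
    kind: str  # "two-center" | "multicenter"

    @property
    def size(self) -> int:
        return len(self.orbitals)


@dataclass
class CASSpace:
    active_coeffs: np.ndarray
    closed_coeffs: np.ndarray
    virtual_coeffs: np.ndarray
    n_active_electrons: int
    cluster: BondCluster
    non_active_occupations: np.ndarray = field(default=None)

    @property
    def n_active_orbitals(self) -> int:
        return self.active_coeffs.shape[1]

    @property
    def n_closed(self) -> int:
        return self.closed_coeffs.shape[1]


def build_correlation_graph(
    solution,
    atom_of: np.ndarray,
    eta: float = DEFAULT_ETA,
) -> CorrelationGraph:
    """Mutual-information graph over the orbitals of ``solution``.

    Edges appear exactly where I_ij > eta * I_max, restricted to inter-center
    pairs; intra-atom correlations are recorded in ``mutual_info`` but never
    create edges.
    """
    atom_of = np.asarray(atom_of)
    n = len(atom_of)
    imat = np.zeros((n, n))
    entropies = np.array(
        [one_orbital_rdm(solution, i).entropy() for i in range(n)]
    )
    g = nx.Graph()
    g.add_nodes_from(range(n))
    thresh = eta * I_MAX
    for i in range(n):
        for j in range(i + 1, n):
            val = mutual_information(solution, i, j)
            imat[i, j] = imat[j, i] = val
            if atom_of[i] != atom_of[j] and val > thresh:
                g.add_edge(i, j, weight=val)
    return CorrelationGraph(g, float(eta), atom_of, entropies, imat)


def detect_bond_clusters(graph: CorrelationGraph) -> list[BondCluster]:
    """Connected components with >= 2 orbitals, ordered by size (descending)
    then by lowest orbital index."""
    out = []
    for comp in nx.connected_components(graph.graph):
        comp = tuple(sorted(comp))
        if len(comp) < 2:
            continue
        atoms = tuple(sorted({int(graph.atom_of[i]) for i in comp}))
        kind = "two-center" if len(comp) == 2 else "multicenter"
        out.append(BondCluster(comp, atoms, kind))
    out.sort(key=lambda c: (-c.size, c.orbitals))
    return out


def best_subset_of_size(graph: CorrelationGraph, k: int) -> tuple | None:
    """Fallback for negative controls: when no cluster of size >= k exists,
    assemble k orbitals from *whole* detected clusters (so no bond partner is
    left dangling), choosing the cluster combination with the largest total
    internal mutual information.

    Splitting bonds would leave half-occupied partners in the non-active
    space and corrupt the closed/virtual classification; unions of complete
    clusters keep the non-active occupations near {0, 2}.  Returns None when
    the graph carries no inter-center correlation at all.
    """
    imat = graph.mutual_info
    n = imat.shape[0]
    if n < k:
        return None
    inter = graph.atom_of[:, None] != graph.atom_of[None, :]
    if not inter.any() or imat[inter].max() < 1e-8:
        return None
    units = [list(c.orbitals) for c in detect_bond_clusters(graph)]
    units += [[v] for v in graph.isolated_orbitals()]

    def internal_weight(sub):
        return sum(imat[a, b] for a, b in combinations(sorted(sub), 2))

    best, best_val = None, -1.0
    count = 0
    for r in range(1, min(k, len(units)) + 1):
        for combo in combinations(range(len(units)), r):
            if sum(len(units[u]) for u in combo) != k:
                continue
            count += 1
            if count > 20000:
                break
            sub = tuple(sorted(o for u in combo for o in units[u]))
            val = internal_weight(sub)
            if val > best_val:
                best, best_val = sub, val
        if count > 20000:
            break
    if best is not None:
        return best
    # no exact-size union exists: rank orbitals inside the strongest
    # low-threshold component and take the top-I k-subset
    pool = sorted(range(n), key=lambda v: -imat[v].sum())[: max(k, 16)]
    best, best_val = None, -1.0
    for sub in combinations(sorted(pool), k):
        val = internal_weight(sub)
        if val > best_val:
            best, best_val = sub, val
    return tuple(best)


def ring_restricted_unions(
    graph: CorrelationGraph, clusters: list[BondCluster], k: int, max_candidates: int = 60
) -> list[tuple]:
    """Candidate k-orbital subsets built from whole clusters whose atoms all
    lie on the largest cycle of the atom-level bonding graph.

    Used for ring negative controls ("highest k-orbital GME"): candidates are
    ranked by internal mutual information; the caller scores them (e.g. by
    GME) and keeps the best.  Empty when the molecule has no bonded ring.
    """
    atom_graph = nx.Graph()
    for c in clusters:
        for a, b in combinations(c.atoms, 2):
            atom_graph.add_edge(a, b)
    cycles = nx.cycle_basis(atom_graph) if atom_graph.number_of_nodes() else []
    if not cycles:
        return []
    ring = set(max(cycles, key=len))
    units = [
        list(c.orbitals) for c in clusters if set(c.atoms) <= ring
    ]
    if not units:
        return []
    imat = graph.mutual_info
    cands = []
    for r in range(1, len(units) + 1):
        for combo in combinations(range(len(units)), r):
            if sum(len(units[u]) for u in combo) != k:
                continue
            sub = tuple(sorted(o for u in combo for o in units[u]))
            w = sum(imat[a, b] for a, b in combinations(sub, 2))
            cands.append((w, sub))
            if len(cands) > 5000:
                break
        if len(cands) > 5000:
            break
    cands.sort(reverse=True)
    return [sub for _, sub in cands[:max_candidates]]


def build_cas_for_cluster(
    gamma: np.ndarray,
    orbital_coeffs: np.ndarray,
    cluster: BondCluster,
    n_electrons: int,
    occupation_window: float = 0.2,
) -> CASSpace:
    """Split the orbital space into (active | closed | virtual) around a bond
    cluster.

    ``gamma`` is the spin-free 1RDM in the localized-orbital basis whose AO
    coefficients are ``orbital_coeffs``.  Natural orbitals of the non-active
    block with occupation > 1 become closed, < 1 virtual; occupations farther
    than ``occupation_window`` from {0, 2} trigger a warning, and occupations
    at exactly 1 are rejected as unclassifiable.
    """
    n = gamma.shape[0]
    active = list(cluster.orbitals)
    rest = [i for i in range(n) if i not in active]
    g_na = gamma[np.ix_(rest, rest)]
    occ, vecs = np.linalg.eigh(g_na)
    occ, vecs = occ[::-1], vecs[:, ::-1]
    if np.any(np.abs(occ - 1.0) < 1e-6):
        raise AmbiguousOccupationError(
            "a non-active natural occupation equals 1.0; closed/virtual "
            "classification is undefined for this state"
        )
    fuzzy = occ[(np.abs(occ - 2.0) > occupation_window) & (np.abs(occ) > occupation_window)]
    if fuzzy.size:
        warnings.warn(
            f"non-active natural occupations far from {{0,2}}: {np.round(fuzzy, 3)}",
            stacklevel=2,
        )
    closed = vecs[:, occ > 1.0]
    virtual = vecs[:, occ < 1.0]
    c_rest = orbital_coeffs[:, rest]
    c_closed = c_rest @ closed
    c_virtual = c_rest @ virtual
    c_active = orbital_coeffs[:, active]
    n_act_elec = int(round(n_electrons - 2 * closed.shape[1]))
    if n_act_elec < 0:
        raise ValueError("negative active electron count; inconsistent 1RDM")
    return CASSpace(
        active_coeffs=c_active,
        closed_coeffs=c_closed,
        virtual_coeffs=c_virtual,
        n_active_electrons=n_act_elec,
        cluster=cluster,
        non_active_occupations=occ,
    )
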