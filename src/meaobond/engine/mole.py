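"""Molecule and contracted-Gaussian shell construction.

Conventions: coordinates stored in Bohr; XYZ input in Angstrom.  Cartesian
shell components are ordered lexicographically (lx descending, then ly);
spherical AOs per shell are ordered m = -l..l.  Primitive coefficients are
stored with the axial Cartesian normalization folded in, and each contracted
shell is scaled to unit self-overlap of its spherical components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .basis import load_basis, normalize_basis_name

__all__ = ["Molecule", "read_xyz", "ELEMENTS", "cart_components", "c2s_matrix"]

ANGSTROM = 1.0 / 0.52917721092

ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5,
    "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
}

#: number of core (non-valence) electrons per element, for reporting only
_DF = {}


def _double_factorial(n: int) -> float:
    if n <= 0:
        return 1.0
    out = 1.0
    while n > 0:
        out *= n
        n -= 2
    return out


@lru_cache(maxsize=8)
def cart_components(l: int) -> tuple[tuple[int, int, int], ...]:
    comps = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            comps.append((lx, ly, l - lx - ly))
    return tuple(comps)


def _gauss_moment(n: int, p: float) -> float:
    """Integral of x^n exp(-p x^2) over the real line."""
    if n % 2:
        return 0.0
    k = n // 2
    return _double_factorial(2 * k - 1) / (2 * p) ** k * np.sqrt(np.pi / p)


def _cart_overlap_same_center(l: int, p: float) -> np.ndarray:
    comps = cart_components(l)
    n = len(comps)
    s = np.zeros((n, n))
    for a, (ix, iy, iz) in enumerate(comps):
        for b, (jx, jy, jz) in enumerate(comps):
            s[a, b] = (
                _gauss_moment(ix + jx, p)
                * _gauss_moment(iy + jy, p)
                * _gauss_moment(iz + jz, p)
            )
    return s


def _real_sph_values(l: int, pts: np.ndarray) -> np.ndarray:
    """Real spherical harmonics (m = -l..l) at unit vectors ``pts``."""
    from scipy.special import sph_harm_y

    theta = np.arccos(np.clip(pts[:, 2], -1, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    out = np.zeros((2 * l + 1, len(pts)))
    for m in range(-l, l + 1):
        am = abs(m)
        y = sph_harm_y(l, am, theta, phi)
        if m == 0:
            out[l + m] = np.real(y)
        elif m > 0:
            out[l + m] = np.sqrt(2.0) * (-1.0) ** m * np.real(y)
        else:
            out[l + m] = np.sqrt(2.0) * (-1.0) ** am * np.imag(y)
    return out


@lru_cache(maxsize=8)
def c2s_matrix(l: int) -> np.ndarray:
    """(2l+1, ncart) transform from raw Cartesian components to orthonormal
    real-spherical components, numerically exact to machine precision.

    Rows are solid-harmonic polynomial coefficients normalized against the
    Cartesian self-overlap metric; the overall shell normalization is applied
    separately, so only the relative row structure matters here.
    """
    comps = cart_components(l)
    rng = np.random.default_rng(7)
    pts = rng.standard_normal((max(60, 6 * len(comps)), 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    mono = np.stack(
        [pts[:, 0] ** ix * pts[:, 1] ** iy * pts[:, 2] ** iz for ix, iy, iz in comps],
        axis=1,
    )
    sph = _real_sph_values(l, pts)  # r^l * Y on unit sphere
    coef, *_ = np.linalg.lstsq(mono, sph.T, rcond=None)
    rows = coef.T  # (2l+1, ncart)
    metric = _cart_overlap_same_center(l, 2.0)  # a=b=1 primitives
    for m in range(2 * l + 1):
        rows[m] /= np.sqrt(rows[m] @ metric @ rows[m])
    # clean numerically-zero entries
    rows[np.abs(rows) < 1e-12] = 0.0
    return rows


def _axial_norm(l: int, a: float) -> float:
    """Normalization of the (l,0,0) Cartesian primitive x^l exp(-a r^2)."""
    s = _gauss_moment(2 * l, 2 * a) * _gauss_moment(0, 2 * a) ** 2
    return 1.0 / np.sqrt(s)


@dataclass
class Shell:
    atom: int
    l: int
    exps: np.ndarray
    coefs: np.ndarray
    center: np.ndarray

    @property
    def nao(self) -> int:
        return 2 * self.l + 1

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def read_xyz(source) -> tuple[list[tuple[str, np.ndarray]], str]:
    """Parse XYZ content (path or literal string); coordinates in Angstrom."""
    text = source
    p = Path(str(source))
    if "\n" not in str(source) and p.exists():
        text = p.read_text()
    lines = [ln for ln in str(text).splitlines()]
    if not lines:
        raise ValueError("empty XYZ input")
    try:
        natom = int(lines[0].split()[0])
        comment = lines[1] if len(lines) > 1 else ""
        body = lines[2 : 2 + natom]
    except (ValueError, IndexError):
        # headerless variant: every line is "symbol x y z"
        comment = ""
        body = [ln for ln in lines if ln.strip()]
    atoms = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ line: {ln!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENTS:
            raise ValueError(f"unknown element symbol {parts[0]!r}")
        atoms.append((sym, np.array([float(x) for x in parts[1:4]])))
    return atoms, comment


class Molecule:
    """Geometry plus a contracted spherical Gaussian basis."""

    def __init__(self, atoms, basis: str, charge: int = 0):
        if isinstance(atoms, (str, Path)):
            atoms, _ = read_xyz(atoms)
        self.atoms = [(sym, np.asarray(xyz, float)) for sym, xyz in atoms]
        self.basis_name = normalize_basis_name(basis)
        self.charge = int(charge)
        self.coords = np.array([xyz for _, xyz in self.atoms]) * ANGSTROM
        self.symbols = [sym for sym, _ in self.atoms]
        self.charges = np.array([ELEMENTS[s] for s in self.symbols], float)
        self.nelectron = int(self.charges.sum()) - self.charge
        self.shells: list[Shell] = []
        self._build_shells()

    # -- construction -----------------------------------------------------

    def _build_shells(self):
        lib = load_basis(self.basis_name)
        for ia, sym in enumerate(self.symbols):
            if sym not in lib:
                raise KeyError(f"basis {self.basis_name!r} has no element {sym}")
            for l, exps, coefs in lib[sym]:
                c = np.array(
                    [cf * _axial_norm(l, a) for a, cf in zip(exps, coefs)]
                )
                # unit self-overlap of the contracted spherical components
                p = exps[:, None] + exps[None, :]
                s_ax = np.zeros_like(p)
                comps0 = cart_components(l)
                rows = c2s_matrix(l)
                scart = np.zeros((len(comps0), len(comps0)))
                for i, ai in enumerate(exps):
                    for j, aj in enumerate(exps):
                        scart += c[i] * c[j] * _cart_overlap_same_center(l, ai + aj)
                ssph = rows @ scart @ rows.T
                c = c / np.sqrt(ssph[0, 0])
                self.shells.append(
                    Shell(ia, l, np.asarray(exps, float), c, self.coords[ia])
                )
        self.nshell = len(self.shells)
        self.ao_loc = np.zeros(self.nshell + 1, dtype=np.int64)
        for i, sh in enumerate(self.shells):
            self.ao_loc[i + 1] = self.ao_loc[i] + sh.nao
        self.nao = int(self.ao_loc[-1])
        self._flatten()

    def _flatten(self):
        """Primitive arrays consumed by the numba integral kernels."""
        self.shell_l = np.array([sh.l for sh in self.shells], dtype=np.int64)
        self.shell_atom = np.array([sh.atom for sh in self.shells], dtype=np.int64)
        self.shell_nprim = np.array(
            [len(sh.exps) for sh in self.shells], dtype=np.int64
        )
        self.shell_pptr = np.zeros(self.nshell + 1, dtype=np.int64)
        for i, sh in enumerate(self.shells):
            self.shell_pptr[i + 1] = self.shell_pptr[i] + len(sh.exps)
        self.prim_exp = np.concatenate([sh.exps for sh in self.shells])
        self.prim_coef = np.concatenate([sh.coefs for sh in self.shells])
        self.shell_center = np.array([sh.center for sh in self.shells])

    # -- metadata ----------------------------------------------------------

    def ao_labels(self) -> list[tuple[int, str, int, int]]:
        """Per-AO (atom index, element symbol, l, m)."""
        out = []
        for sh in self.shells:
            for m in range(-sh.l, sh.l + 1):
                out.append((sh.atom, self.symbols[sh.atom], sh.l, m))
        return out

    def ao_atom_map(self) -> np.ndarray:
        return np.array([lbl[0] for lbl in self.ao_labels()], dtype=np.int64)

    @property
    def natom(self) -> int:
        return len(self.atoms)

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.natom):
            for j in range(i + 1, self.natom):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                e += self.charges[i] * self.charges[j] / r
        return float(e)

    def with_basis(self, basis: str) -> "Molecule":
        return Molecule(self.atoms, basis, self.charge)

    def __repr__(self):
        return (
            f"Molecule({'+'.join(self.symbols)}, basis={self.basis_name}, "
            f"charge={self.charge}, nao={self.nao})"
        )
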