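"""AO evaluation on real-space grids and Gaussian cube export."""

from __future__ import annotations

import numpy as np

from .mole import Molecule, c2s_matrix, cart_components

__all__ = ["eval_ao", "write_cube"]


def eval_ao(mol: Molecule, points: np.ndarray) -> np.ndarray:
    """Values of all (spherical) AOs at Cartesian ``points`` (Bohr).

    Returns array (npoints, nao).
    """
    points = np.asarray(points, float)
    out = np.zeros((len(points), mol.nao))
    for ish, sh in enumerate(mol.shells):
        d = points - sh.center[None, :]
        r2 = np.einsum("pi,pi->p", d, d)
        radial = np.zeros(len(points))
        for a, c in zip(sh.exps, sh.coefs):
            radial += c * np.exp(-a * r2)
        comps = cart_components(sh.l)
        cart = np.stack(
            [
                d[:, 0] ** ix * d[:, 1] ** iy * d[:, 2] ** iz
                for ix, iy, iz in comps
            ],
            axis=1,
        )
        sph = cart @ c2s_matrix(sh.l).T
        lo = mol.ao_loc[ish]
        out[:, lo : lo + sh.nao] = radial[:, None] * sph
    return out


def write_cube(
    mol: Molecule,
    coeff: np.ndarray,
    path,
    spacing: float = 0.25,
    margin: float = 4.0,
    comment: str = "orbital",
):
    """Write one orbital (AO coefficient vector) as a Gaussian cube file.

    ``spacing`` and ``margin`` in Bohr.
    """
    lo = mol.coords.min(axis=0) - margin
    hi = mol.coords.max(axis=0) + margin
    npts = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [np.linspace(lo[k], lo[k] + spacing * (npts[k] - 1), npts[k]) for k in range(3)]
    with open(path, "w") as f:
        f.write("meaobond cube\n")
        f.write(f"{comment}\n")
        f.write(f"{mol.natom:5d} {lo[0]:12.6f} {lo[1]:12.6f} {lo[2]:12.6f}\n")
        f.write(f"{npts[0]:5d} {spacing:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        f.write(f"{npts[1]:5d} {0.0:12.6f} {spacing:12.6f} {0.0:12.6f}\n")
        f.write(f"{npts[2]:5d} {0.0:12.6f} {0.0:12.6f} {spacing:12.6f}\n")
        for z, xyz in zip(mol.charges, mol.coords):
            f.write(
                f"{int(z):5d} {z:12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n"
            )
        for ix in range(npts[0]):
            for iy in range(npts[1]):
                pts = np.array(
                    [[axes[0][ix], axes[1][iy], z] for z in axes[2]]
                )
                vals = eval_ao(mol, pts) @ coeff
                for k in range(0, len(vals), 6):
                    f.write(
                        " ".join(f"{v:13.5E}" for v in vals[k : k + 6]) + "\n"
                    )
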