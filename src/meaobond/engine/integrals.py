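"""McMurchie-Davidson Gaussian integrals (numba-jitted kernels).

Provides overlap, kinetic, nuclear-attraction, and the two- and three-center
Coulomb integrals needed for density-fitted SCF and CASCI.  Kernels work on
raw Cartesian components; the spherical transformation is applied in numpy
using the shell-wise matrices from :mod:`meaobond.engine.mole`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .mole import Molecule, c2s_matrix, cart_components

__all__ = [
    "overlap",
    "overlap_cross",
    "kinetic",
    "nuclear_attraction",
    "coulomb_2c",
    "coulomb_3c",
]

_PRIM_SCREEN = 1e-14


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boys(mmax, t, out):
    if t < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if t < 35.0:
        # series for the highest order, then downward recursion
        term = 1.0 / (2.0 * mmax + 1.0)
        acc = term
        k = 1
        while True:
            term *= 2.0 * t / (2.0 * mmax + 2.0 * k + 1.0)
            acc += term
            if term < 1e-17 * acc or k > 200:
                break
            k += 1
        et = np.exp(-t)
        out[mmax] = acc * et
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * t * out[m + 1] + et) / (2.0 * m + 1.0)
    else:
        out[0] = 0.5 * np.sqrt(np.pi / t)
        et = np.exp(-t)
        for m in range(mmax):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - et) / (2.0 * t)


@njit(cache=True)
def _e_table_1d(la, lb, a, b, ab, e):
    """Hermite expansion coefficients E[i, j, t] for one dimension.

    ``ab`` is A - B along this axis; table shape (la+1, lb+1, la+lb+1).
    """
    p = a + b
    mu = a * b / p
    pa = -b / p * ab  # P - A
    pb = a / p * ab  # P - B
    e[:, :, :] = 0.0
    e[0, 0, 0] = np.exp(-mu * ab * ab)
    inv2p = 0.5 / p
    for i in range(la):
        for t in range(i + 1):
            e[i + 1, 0, t] += pa * e[i, 0, t]
            e[i + 1, 0, t + 1] += inv2p * e[i, 0, t]
        for t in range(1, i + 2):
            e[i + 1, 0, t - 1] += t * e[i, 0, t]
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 1):
                e[i, j + 1, t] += pb * e[i, j, t]
                e[i, j + 1, t + 1] += inv2p * e[i, j, t]
            for t in range(1, i + j + 2):
                e[i, j + 1, t - 1] += t * e[i, j, t]


@njit(cache=True)
def _r_table(lmax, alpha, pc, r):
    """Hermite Coulomb integrals R[t, u, v] up to total order lmax."""
    boys = np.empty(lmax + 1)
    t2 = alpha * (pc[0] * pc[0] + pc[1] * pc[1] + pc[2] * pc[2])
    _boys(lmax, t2, boys)
    n1 = lmax + 1
    rn = np.zeros((n1, n1, n1, n1))
    for n in range(n1):
        rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * boys[n]
    for total in range(1, n1):
        for n in range(n1 - total):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = pc[0] * rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = pc[1] * rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * rn[n + 1, t, u - 2, v]
                    else:
                        val = pc[2] * rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * rn[n + 1, t, u, v - 2]
                    rn[n, t, u, v] = val
    r[:, :, :] = rn[0]


@njit(cache=True)
def _comp_list(l):
    n = (l + 1) * (l + 2) // 2
    out = np.empty((n, 3), dtype=np.int64)
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out[k, 0] = lx
            out[k, 1] = ly
            out[k, 2] = l - lx - ly
            k += 1
    return out


# ---------------------------------------------------------------------------
# one-electron integrals
# ---------------------------------------------------------------------------


@njit(cache=True)
def _overlap_kinetic_kernel(
    shell_l, shell_nprim, shell_pptr, prim_exp, prim_coef, centers, s_out, t_out, loc
):
    nsh = len(shell_l)
    for ish in range(nsh):
        la = shell_l[ish]
        ca = _comp_list(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            cb = _comp_list(lb)
            ab = centers[ish] - centers[jsh]
            nca = ca.shape[0]
            ncb = cb.shape[0]
            sblk = np.zeros((nca, ncb))
            tblk = np.zeros((nca, ncb))
            ex = np.zeros((la + 1, lb + 3, la + lb + 3))
            ey = np.zeros((la + 1, lb + 3, la + lb + 3))
            ez = np.zeros((la + 1, lb + 3, la + lb + 3))
            for ip in range(shell_pptr[ish], shell_pptr[ish + 1]):
                a = prim_exp[ip]
                for jp in range(shell_pptr[jsh], shell_pptr[jsh + 1]):
                    b = prim_exp[jp]
                    cc = prim_coef[ip] * prim_coef[jp]
                    p = a + b
                    fac = (np.pi / p) ** 1.5
                    if abs(cc) * fac * np.exp(
                        -a * b / p * (ab[0] ** 2 + ab[1] ** 2 + ab[2] ** 2)
                    ) < _PRIM_SCREEN:
                        continue
                    _e_table_1d(la, lb + 2, a, b, ab[0], ex)
                    _e_table_1d(la, lb + 2, a, b, ab[1], ey)
                    _e_table_1d(la, lb + 2, a, b, ab[2], ez)
                    for ia in range(nca):
                        ix, iy, iz = ca[ia, 0], ca[ia, 1], ca[ia, 2]
                        for ib in range(ncb):
                            jx, jy, jz = cb[ib, 0], cb[ib, 1], cb[ib, 2]
                            sx = ex[ix, jx, 0]
                            sy = ey[iy, jy, 0]
                            sz = ez[iz, jz, 0]
                            sblk[ia, ib] += cc * fac * sx * sy * sz
                            # kinetic: 1D operator applied along each axis
                            tx = b * (2 * jx + 1) * sx - 2 * b * b * ex[ix, jx + 2, 0]
                            if jx >= 2:
                                tx -= 0.5 * jx * (jx - 1) * ex[ix, jx - 2, 0]
                            ty = b * (2 * jy + 1) * sy - 2 * b * b * ey[iy, jy + 2, 0]
                            if jy >= 2:
                                ty -= 0.5 * jy * (jy - 1) * ey[iy, jy - 2, 0]
                            tz = b * (2 * jz + 1) * sz - 2 * b * b * ez[iz, jz + 2, 0]
                            if jz >= 2:
                                tz -= 0.5 * jz * (jz - 1) * ez[iz, jz - 2, 0]
                            tblk[ia, ib] += cc * fac * (
                                tx * sy * sz + sx * ty * sz + sx * sy * tz
                            )
            s_out[loc[ish] : loc[ish] + nca, loc[jsh] : loc[jsh] + ncb] = sblk
            t_out[loc[ish] : loc[ish] + nca, loc[jsh] : loc[jsh] + ncb] = tblk


@njit(cache=True)
def _nuclear_kernel(
    shell_l,
    shell_nprim,
    shell_pptr,
    prim_exp,
    prim_coef,
    centers,
    atom_coords,
    atom_charges,
    v_out,
    loc,
):
    nsh = len(shell_l)
    natm = atom_coords.shape[0]
    for ish in range(nsh):
        la = shell_l[ish]
        ca = _comp_list(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            cb = _comp_list(lb)
            ab = centers[ish] - centers[jsh]
            nca = ca.shape[0]
            ncb = cb.shape[0]
            vblk = np.zeros((nca, ncb))
            lsum = la + lb
            ex = np.zeros((la + 1, lb + 1, lsum + 1))
            ey = np.zeros((la + 1, lb + 1, lsum + 1))
            ez = np.zeros((la + 1, lb + 1, lsum + 1))
            rt = np.zeros((lsum + 1, lsum + 1, lsum + 1))
            pc = np.zeros(3)
            for ip in range(shell_pptr[ish], shell_pptr[ish + 1]):
                a = prim_exp[ip]
                for jp in range(shell_pptr[jsh], shell_pptr[jsh + 1]):
                    b = prim_exp[jp]
                    cc = prim_coef[ip] * prim_coef[jp]
                    p = a + b
                    kab = np.exp(
                        -a * b / p * (ab[0] ** 2 + ab[1] ** 2 + ab[2] ** 2)
                    )
                    if abs(cc) * kab * (np.pi / p) ** 1.5 < _PRIM_SCREEN:
                        continue
                    _e_table_1d(la, lb, a, b, ab[0], ex)
                    _e_table_1d(la, lb, a, b, ab[1], ey)
                    _e_table_1d(la, lb, a, b, ab[2], ez)
                    px = (a * centers[ish, 0] + b * centers[jsh, 0]) / p
                    py = (a * centers[ish, 1] + b * centers[jsh, 1]) / p
                    pz = (a * centers[ish, 2] + b * centers[jsh, 2]) / p
                    pref = cc * 2.0 * np.pi / p
                    for iat in range(natm):
                        pc[0] = px - atom_coords[iat, 0]
                        pc[1] = py - atom_coords[iat, 1]
                        pc[2] = pz - atom_coords[iat, 2]
                        _r_table(lsum, p, pc, rt)
                        z = atom_charges[iat]
                        for ia in range(nca):
                            ix, iy, iz = ca[ia, 0], ca[ia, 1], ca[ia, 2]
                            for ib in range(ncb):
                                jx, jy, jz = cb[ib, 0], cb[ib, 1], cb[ib, 2]
                                acc = 0.0
                                for t in range(ix + jx + 1):
                                    extx = ex[ix, jx, t]
                                    if extx == 0.0:
                                        continue
                                    for u in range(iy + jy + 1):
                                        eyu = ey[iy, jy, u]
                                        if eyu == 0.0:
                                            continue
                                        for v in range(iz + jz + 1):
                                            acc += (
                                                extx
                                                * eyu
                                                * ez[iz, jz, v]
                                                * rt[t, u, v]
                                            )
                                vblk[ia, ib] -= z * pref * acc
            v_out[loc[ish] : loc[ish] + nca, loc[jsh] : loc[jsh] + ncb] = vblk


# ---------------------------------------------------------------------------
# two- and three-center Coulomb integrals
# ---------------------------------------------------------------------------


@njit(cache=True)
def _coulomb_2c_kernel(
    shell_l, shell_pptr, prim_exp, prim_coef, centers, out, loc
):
    nsh = len(shell_l)
    for ish in range(nsh):
        la = shell_l[ish]
        ca = _comp_list(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            cb = _comp_list(lb)
            nca = ca.shape[0]
            ncb = cb.shape[0]
            blk = np.zeros((nca, ncb))
            lsum = la + lb
            rt = np.zeros((lsum + 1, lsum + 1, lsum + 1))
            ea = np.zeros((la + 1, 1, la + 1))
            eb = np.zeros((lb + 1, 1, lb + 1))
            pc = centers[ish] - centers[jsh]
            for ip in range(shell_pptr[ish], shell_pptr[ish + 1]):
                a = prim_exp[ip]
                _e_table_1d(la, 0, a, 0.0, 0.0, ea)
                for jp in range(shell_pptr[jsh], shell_pptr[jsh + 1]):
                    b = prim_exp[jp]
                    _e_table_1d(lb, 0, b, 0.0, 0.0, eb)
                    cc = prim_coef[ip] * prim_coef[jp]
                    alpha = a * b / (a + b)
                    pref = (
                        cc
                        * 2.0
                        * np.pi ** 2.5
                        / (a * b * np.sqrt(a + b))
                    )
                    _r_table(lsum, alpha, pc, rt)
                    for ia in range(nca):
                        ix, iy, iz = ca[ia, 0], ca[ia, 1], ca[ia, 2]
                        for ib in range(ncb):
                            jx, jy, jz = cb[ib, 0], cb[ib, 1], cb[ib, 2]
                            acc = 0.0
                            for t in range(ix + 1):
                                eat = ea[ix, 0, t]
                                if eat == 0.0:
                                    continue
                                for u in range(iy + 1):
                                    eau = ea[iy, 0, u]
                                    if eau == 0.0:
                                        continue
                                    for v in range(iz + 1):
                                        eav = ea[iz, 0, v]
                                        if eav == 0.0:
                                            continue
                                        h = eat * eau * eav
                                        for tt in range(jx + 1):
                                            ebt = eb[jx, 0, tt]
                                            if ebt == 0.0:
                                                continue
                                            for uu in range(jy + 1):
                                                ebu = eb[jy, 0, uu]
                                                if ebu == 0.0:
                                                    continue
                                                for vv in range(jz + 1):
                                                    ebv = eb[jz, 0, vv]
                                                    if ebv == 0.0:
                                                        continue
                                                    sign = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                    acc += (
                                                        h
                                                        * ebt
                                                        * ebu
                                                        * ebv
                                                        * sign
                                                        * rt[t + tt, u + uu, v + vv]
                                                    )
                            blk[ia, ib] += pref * acc
            out[loc[ish] : loc[ish] + nca, loc[jsh] : loc[jsh] + ncb] = blk


@njit(cache=True)
def _coulomb_3c_kernel(
    shell_l,
    shell_pptr,
    prim_exp,
    prim_coef,
    centers,
    aux_l,
    aux_pptr,
    aux_exp,
    aux_coef,
    aux_centers,
    out,
    loc,
    aux_loc,
):
    nsh = len(shell_l)
    naux_sh = len(aux_l)
    for ish in range(nsh):
        la = shell_l[ish]
        ca = _comp_list(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            cb = _comp_list(lb)
            nca = ca.shape[0]
            ncb = cb.shape[0]
            lab = la + lb
            ab = centers[ish] - centers[jsh]
            rab2 = ab[0] ** 2 + ab[1] ** 2 + ab[2] ** 2
            ex = np.zeros((la + 1, lb + 1, lab + 1))
            ey = np.zeros((la + 1, lb + 1, lab + 1))
            ez = np.zeros((la + 1, lb + 1, lab + 1))
            pc = np.zeros(3)
            for ip in range(shell_pptr[ish], shell_pptr[ish + 1]):
                a = prim_exp[ip]
                for jp in range(shell_pptr[jsh], shell_pptr[jsh + 1]):
                    b = prim_exp[jp]
                    cc = prim_coef[ip] * prim_coef[jp]
                    p = a + b
                    kab = np.exp(-a * b / p * rab2)
                    if abs(cc) * kab / p < _PRIM_SCREEN:
                        continue
                    _e_table_1d(la, lb, a, b, ab[0], ex)
                    _e_table_1d(la, lb, a, b, ab[1], ey)
                    _e_table_1d(la, lb, a, b, ab[2], ez)
                    px = (a * centers[ish, 0] + b * centers[jsh, 0]) / p
                    py = (a * centers[ish, 1] + b * centers[jsh, 1]) / p
                    pz = (a * centers[ish, 2] + b * centers[jsh, 2]) / p
                    for ksh in range(naux_sh):
                        lc = aux_l[ksh]
                        cc_list = _comp_list(lc)
                        ncc = cc_list.shape[0]
                        ltot = lab + lc
                        rt = np.zeros((ltot + 1, ltot + 1, ltot + 1))
                        ec = np.zeros((lc + 1, 1, lc + 1))
                        pc[0] = px - aux_centers[ksh, 0]
                        pc[1] = py - aux_centers[ksh, 1]
                        pc[2] = pz - aux_centers[ksh, 2]
                        for kp in range(aux_pptr[ksh], aux_pptr[ksh + 1]):
                            q = aux_exp[kp]
                            cq = aux_coef[kp]
                            alpha = p * q / (p + q)
                            pref = (
                                cc
                                * cq
                                * 2.0
                                * np.pi ** 2.5
                                / (p * q * np.sqrt(p + q))
                            )
                            _e_table_1d(lc, 0, q, 0.0, 0.0, ec)
                            _r_table(ltot, alpha, pc, rt)
                            for ia in range(nca):
                                ix, iy, iz = ca[ia, 0], ca[ia, 1], ca[ia, 2]
                                for ib in range(ncb):
                                    jx, jy, jz = cb[ib, 0], cb[ib, 1], cb[ib, 2]
                                    for ic in range(ncc):
                                        kx, ky, kz = (
                                            cc_list[ic, 0],
                                            cc_list[ic, 1],
                                            cc_list[ic, 2],
                                        )
                                        acc = 0.0
                                        for t in range(ix + jx + 1):
                                            ext = ex[ix, jx, t]
                                            if ext == 0.0:
                                                continue
                                            for u in range(iy + jy + 1):
                                                eyu = ey[iy, jy, u]
                                                if eyu == 0.0:
                                                    continue
                                                for v in range(iz + jz + 1):
                                                    ezv = ez[iz, jz, v]
                                                    if ezv == 0.0:
                                                        continue
                                                    h = ext * eyu * ezv
                                                    for tt in range(kx + 1):
                                                        ect = ec[kx, 0, tt]
                                                        if ect == 0.0:
                                                            continue
                                                        for uu in range(ky + 1):
                                                            ecu = ec[ky, 0, uu]
                                                            if ecu == 0.0:
                                                                continue
                                                            for vv in range(kz + 1):
                                                                ecv = ec[kz, 0, vv]
                                                                if ecv == 0.0:
                                                                    continue
                                                                sign = (
                                                                    1.0
                                                                    if (tt + uu + vv) % 2 == 0
                                                                    else -1.0
                                                                )
                                                                acc += (
                                                                    h
                                                                    * ect
                                                                    * ecu
                                                                    * ecv
                                                                    * sign
                                                                    * rt[
                                                                        t + tt,
                                                                        u + uu,
                                                                        v + vv,
                                                                    ]
                                                                )
                                        out[
                                            loc[ish] + ia,
                                            loc[jsh] + ib,
                                            aux_loc[ksh] + ic,
                                        ] += pref * acc


# ---------------------------------------------------------------------------
# python-facing wrappers (Cartesian -> spherical)
# ---------------------------------------------------------------------------


def _cart_locs(mol: Molecule) -> np.ndarray:
    loc = np.zeros(mol.nshell + 1, dtype=np.int64)
    for i, sh in enumerate(mol.shells):
        loc[i + 1] = loc[i] + sh.ncart
    return loc


def _sph_transform(mol: Molecule) -> np.ndarray:
    """(ncart_total, nsph_total) block-diagonal Cartesian->spherical matrix."""
    loc = _cart_locs(mol)
    t = np.zeros((int(loc[-1]), mol.nao))
    for i, sh in enumerate(mol.shells):
        rows = c2s_matrix(sh.l)  # (nsph, ncart)
        t[loc[i] : loc[i + 1], mol.ao_loc[i] : mol.ao_loc[i + 1]] = rows.T
    return t


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return np.tril(m) + np.tril(m, -1).T


def overlap(mol: Molecule) -> np.ndarray:
    return _one_electron(mol)[0]


def kinetic(mol: Molecule) -> np.ndarray:
    return _one_electron(mol)[1]


def _one_electron(mol: Molecule):
    loc = _cart_locs(mol)
    n = int(loc[-1])
    s = np.zeros((n, n))
    t = np.zeros((n, n))
    _overlap_kinetic_kernel(
        mol.shell_l,
        mol.shell_nprim,
        mol.shell_pptr,
        mol.prim_exp,
        mol.prim_coef,
        mol.shell_center,
        s,
        t,
        loc,
    )
    s = _symmetrize(s)
    t = _symmetrize(t)
    tr = _sph_transform(mol)
    return tr.T @ s @ tr, tr.T @ t @ tr


def overlap_cross(mol_a: Molecule, mol_b: Molecule) -> np.ndarray:
    """Overlap between the AO bases of two molecules with identical geometry
    (or generally, any two shell sets)."""
    import copy

    merged = copy.copy(mol_a)
    merged.shells = mol_a.shells + mol_b.shells
    merged.nshell = len(merged.shells)
    merged.ao_loc = np.zeros(merged.nshell + 1, dtype=np.int64)
    for i, sh in enumerate(merged.shells):
        merged.ao_loc[i + 1] = merged.ao_loc[i] + sh.nao
    merged.nao = int(merged.ao_loc[-1])
    merged._flatten()
    s_full = overlap(merged)
    return s_full[: mol_a.nao, mol_a.nao :]


def nuclear_attraction(mol: Molecule) -> np.ndarray:
    loc = _cart_locs(mol)
    n = int(loc[-1])
    v = np.zeros((n, n))
    _nuclear_kernel(
        mol.shell_l,
        mol.shell_nprim,
        mol.shell_pptr,
        mol.prim_exp,
        mol.prim_coef,
        mol.shell_center,
        mol.coords,
        mol.charges,
        v,
        loc,
    )
    v = _symmetrize(v)
    tr = _sph_transform(mol)
    return tr.T @ v @ tr


def coulomb_2c(mol: Molecule) -> np.ndarray:
    """(P|Q) Coulomb metric of a (usually auxiliary) basis."""
    loc = _cart_locs(mol)
    n = int(loc[-1])
    out = np.zeros((n, n))
    _coulomb_2c_kernel(
        mol.shell_l,
        mol.shell_pptr,
        mol.prim_exp,
        mol.prim_coef,
        mol.shell_center,
        out,
        loc,
    )
    out = _symmetrize(out)
    tr = _sph_transform(mol)
    return tr.T @ out @ tr


def coulomb_3c(mol: Molecule, aux: Molecule) -> np.ndarray:
    """(mu nu | P) three-center Coulomb tensor, shape (nao, nao, naux)."""
    loc = _cart_locs(mol)
    aux_loc = _cart_locs(aux)
    n = int(loc[-1])
    naux = int(aux_loc[-1])
    out = np.zeros((n, n, naux))
    _coulomb_3c_kernel(
        mol.shell_l,
        mol.shell_pptr,
        mol.prim_exp,
        mol.prim_coef,
        mol.shell_center,
        aux.shell_l,
        aux.shell_pptr,
        aux.prim_exp,
        aux.prim_coef,
        aux.shell_center,
        out,
        loc,
        aux_loc,
    )
    # fill the upper shell-pair triangle
    for i in range(mol.nshell):
        for j in range(i):
            out[loc[j] : loc[j + 1], loc[i] : loc[i + 1], :] = np.transpose(
                out[loc[i] : loc[i + 1], loc[j] : loc[j + 1], :], (1, 0, 2)
            )
    tr = _sph_transform(mol)
    tra = _sph_transform(aux)
    out = np.tensordot(tr.T, out, axes=(1, 0))
    out = np.tensordot(out, tr, axes=(1, 0)).transpose(0, 2, 1)
    out = np.tensordot(out, tra, axes=(2, 0))
    return out
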