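"""Numba force and neighbor-list kernels for the CG simulator."""

from __future__ import annotations

import numpy as np
from numba import njit

from .gayberne import gb_pair
from .params import MODE_GB, MODE_WCA

_WCA_CUT = 2.0 ** (1.0 / 6.0)
_LJ_SWITCH = 0.3  # nm, switching width for attractive LJ channels


@njit(cache=True, fastmath=True)
def _min_image(d, box, periodic):
    for ax in range(3):
        if periodic[ax]:
            L = box[ax]
            if d[ax] > 0.5 * L:
                d[ax] -= L
            elif d[ax] < -0.5 * L:
                d[ax] += L
    return d


@njit(cache=True)
def build_neighbor_pairs(pos, box, periodic, rlist):
    """Half list of particle pairs within ``rlist`` via a cell list."""
    n = pos.shape[0]
    lo = np.empty(3)
    span = np.empty(3)
    for ax in range(3):
        if periodic[ax]:
            lo[ax] = 0.0
            span[ax] = box[ax]
        else:
            mn = pos[0, ax]
            mx = pos[0, ax]
            for i in range(1, n):
                if pos[i, ax] < mn:
                    mn = pos[i, ax]
                if pos[i, ax] > mx:
                    mx = pos[i, ax]
            lo[ax] = mn - 1e-9
            span[ax] = (mx - mn) + 2e-9
    nc = np.empty(3, dtype=np.int64)
    for ax in range(3):
        nc[ax] = max(int(span[ax] / rlist), 1)
        if periodic[ax] and nc[ax] < 3:
            nc[ax] = 1  # too few cells to wrap safely: single cell
    ncx, ncy, ncz = nc[0], nc[1], nc[2]
    ntot = ncx * ncy * ncz
    cw = np.empty(3)
    for ax in range(3):
        cw[ax] = span[ax] / nc[ax]

    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ntot + 1, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - lo[0]) % span[0] / cw[0]) if periodic[0] \
            else int((pos[i, 0] - lo[0]) / cw[0])
        cy = int((pos[i, 1] - lo[1]) % span[1] / cw[1]) if periodic[1] \
            else int((pos[i, 1] - lo[1]) / cw[1])
        cz = int((pos[i, 2] - lo[2]) % span[2] / cw[2]) if periodic[2] \
            else int((pos[i, 2] - lo[2]) / cw[2])
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ntot):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    r2max = rlist * rlist
    cap = max(64 * n, 1024)
    pairs = np.empty((cap, 2), dtype=np.int64)
    npairs = 0
    d = np.empty(3)
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        for oz in range(-1, 2):
                            nx = cx + ox
                            ny = cy + oy
                            nz = cz + oz
                            if periodic[0] and ncx >= 3:
                                nx %= ncx
                            if periodic[1] and ncy >= 3:
                                ny %= ncy
                            if periodic[2] and ncz >= 3:
                                nz %= ncz
                            if (nx < 0 or nx >= ncx or ny < 0 or ny >= ncy
                                    or nz < 0 or nz >= ncz):
                                continue
                            c2 = (nx * ncy + ny) * ncz + nz
                            if c2 < c:
                                continue
                            same = c2 == c
                            for ii in range(count[c], count[c + 1]):
                                i = order[ii]
                                start = ii + 1 if same else count[c2]
                                for jj in range(start, count[c2 + 1]):
                                    j = order[jj]
                                    for ax in range(3):
                                        d[ax] = pos[j, ax] - pos[i, ax]
                                    _min_image(d, box, periodic)
                                    r2 = d[0] * d[0] + d[1] * d[1] \
                                        + d[2] * d[2]
                                    if r2 < r2max:
                                        if npairs >= cap:
                                            cap *= 2
                                            new = np.empty((cap, 2),
                                                           dtype=np.int64)
                                            new[:npairs] = pairs[:npairs]
                                            pairs = new
                                        pairs[npairs, 0] = i
                                        pairs[npairs, 1] = j
                                        npairs += 1
    # deduplicate is unnecessary: half stencil with c2 >= c and same-cell
    # start index guarantee uniqueness
    return pairs[:npairs].copy()


@njit(cache=True, fastmath=True)
def compute_forces(pos, dirs, types, pid, n_lipids, pairs,
                   box, periodic,
                   s0, e0, chi, chip, ea, gb_rc, gb_ron,
                   mode_tab, eps_tab, sig_tab, cut_tab,
                   spring_i, spring_j, spring_k, spring_r0):
    """Forces, director gradients and the energy decomposition.

    Returns (forces (N,3), dir_grad (n_lipids,3), e_lipid, e_spring,
    e_protein_lipid, e_protein_protein).  ``dir_grad`` holds +dU/du.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    g = np.zeros((n_lipids, 3))
    e_ll = 0.0
    e_pl = 0.0
    e_pp = 0.0
    bx, by, bz = box[0], box[1], box[2]
    px, py, pz = periodic[0], periodic[1], periodic[2]
    gb_rc2 = gb_rc * gb_rc
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        pi = pid[i]
        pj = pid[j]
        if pi >= 0 and pi == pj:
            continue  # intra-protein pairs carry springs only
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if px:
            if dx > 0.5 * bx:
                dx -= bx
            elif dx < -0.5 * bx:
                dx += bx
        if py:
            if dy > 0.5 * by:
                dy -= by
            elif dy < -0.5 * by:
                dy += by
        if pz:
            if dz > 0.5 * bz:
                dz -= bz
            elif dz < -0.5 * bz:
                dz += bz
        r2 = dx * dx + dy * dy + dz * dz
        ti = types[i]
        tj = types[j]
        m = mode_tab[ti, tj]
        if m == MODE_GB:
            if r2 >= gb_rc2:
                continue
            (u, fx, fy, fz, g1x, g1y, g1z, g2x, g2y, g2z) = gb_pair(
                dx, dy, dz,
                dirs[i, 0], dirs[i, 1], dirs[i, 2],
                dirs[j, 0], dirs[j, 1], dirs[j, 2],
                s0, e0, chi, chip, ea, gb_rc, gb_ron)
            e_ll += u
            f[j, 0] += fx
            f[j, 1] += fy
            f[j, 2] += fz
            f[i, 0] -= fx
            f[i, 1] -= fy
            f[i, 2] -= fz
            g[i, 0] += g1x
            g[i, 1] += g1y
            g[i, 2] += g1z
            g[j, 0] += g2x
            g[j, 1] += g2y
            g[j, 2] += g2z
        else:
            rc = cut_tab[ti, tj]
            if rc <= 0.0 or r2 >= rc * rc:
                continue
            r = np.sqrt(r2)
            sigma = sig_tab[ti, tj]
            epsi = eps_tab[ti, tj]
            sr2 = sigma * sigma / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            u = 4.0 * epsi * (sr12 - sr6)
            du = 4.0 * epsi * (-12.0 * sr12 + 6.0 * sr6) / r
            if m == MODE_WCA:
                u += epsi
                sw = 1.0
                dsw = 0.0
            else:
                ron = rc - _LJ_SWITCH
                if r <= ron:
                    sw = 1.0
                    dsw = 0.0
                else:
                    t = (r - ron) / (rc - ron)
                    sw = 1.0 + t * t * t * (-10.0 + t * (15.0 - 6.0 * t))
                    dsw = t * t * (-30.0 + t * (60.0 - 30.0 * t)) \
                        / (rc - ron)
            fmag = -(sw * du + dsw * u) / r
            u *= sw
            if pi < 0 or pj < 0:
                e_pl += u
            else:
                e_pp += u
            f[j, 0] += fmag * dx
            f[j, 1] += fmag * dy
            f[j, 2] += fmag * dz
            f[i, 0] -= fmag * dx
            f[i, 1] -= fmag * dy
            f[i, 2] -= fmag * dz
    e_spring = 0.0
    for sp in range(spring_i.shape[0]):
        i = spring_i[sp]
        j = spring_j[sp]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if px:
            if dx > 0.5 * bx:
                dx -= bx
            elif dx < -0.5 * bx:
                dx += bx
        if py:
            if dy > 0.5 * by:
                dy -= by
            elif dy < -0.5 * by:
                dy += by
        if pz:
            if dz > 0.5 * bz:
                dz -= bz
            elif dz < -0.5 * bz:
                dz += bz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - spring_r0[sp]
        e_spring += 0.5 * spring_k[sp] * dr * dr
        fmag = -spring_k[sp] * dr / r
        f[j, 0] += fmag * dx
        f[j, 1] += fmag * dy
        f[j, 2] += fmag * dz
        f[i, 0] -= fmag * dx
        f[i, 1] -= fmag * dy
        f[i, 2] -= fmag * dz
    return f, g, e_ll, e_spring, e_pl, e_pp
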