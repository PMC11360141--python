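"""Numba kernels for the Monte-Carlo voxel-copy sweep.

The incremental energy change of a voxel copy has three parts: the local
contact-energy change over the 26-neighborhood of the target voxel, the
quadratic volume-constraint change of the two affected cells, and the
link-energy change induced by the centroid shifts of those two cells.
A cell emptied by a copy is treated as removed (its links drop to zero
energy); the Python layer prunes it after the sweep.
"""

import numpy as np
from numba import njit

# owner codes
_MEDIUM = 0
_SUBSTRATE = -1

_DX = np.array([1, -1, 0, 0, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1, 0, 0], dtype=np.int64)
_DZ = np.array([0, 0, 0, 0, 1, -1], dtype=np.int64)


@njit(cache=True, inline="always")
def _tcode(o, ctype):
    if o == _MEDIUM:
        return 0
    if o == _SUBSTRATE:
        return 1
    return ctype[o]


@njit(cache=True, inline="always")
def _pair_energy(kind, lam, L0, sat, pax, pay, paz, pbx, pby, pbz):
    dx = pax - pbx
    dy = pay - pby
    dz = paz - pbz
    l = np.sqrt(dx * dx + dy * dy + dz * dz)
    if kind == 2:  # lamellipodium, constant tension
        if sat != 0:
            return 0.0
        return lam * l
    d = l - L0
    return lam * d * d


@njit(cache=True)
def _link_delta_for_cell(c, cs, ct, counted_other,
                         vol, sx, sy, sz,
                         ncsx, ncsy, ncsz, nvs,
                         nctx, ncty, nctz, nvt,
                         lptr, lidx, lkind, la, lb,
                         lax, lay, laz, llam, lL0, lsat):
    """Old-minus-new link energy terms for all links of cell ``c``.

    ``cs``/``ct`` are the gaining/losing cells with their proposed new
    centroids; ``counted_other`` skips links already summed for the other
    affected cell.  Returns (new - old).
    """
    dE = 0.0
    for k in range(lptr[c], lptr[c + 1]):
        li = lidx[k]
        a = la[li]
        b = lb[li]
        if counted_other >= 0 and (a == counted_other or b == counted_other):
            continue
        # endpoint A (always a cell)
        oax = sx[a] / vol[a]
        oay = sy[a] / vol[a]
        oaz = sz[a] / vol[a]
        dead_new = False
        if a == cs:
            nax, nay, naz = ncsx, ncsy, ncsz
        elif a == ct:
            if nvt == 0:
                dead_new = True
                nax, nay, naz = oax, oay, oaz
            else:
                nax, nay, naz = nctx, ncty, nctz
        else:
            nax, nay, naz = oax, oay, oaz
        # endpoint B (cell or fixed anchor)
        if b >= 0:
            obx = sx[b] / vol[b]
            oby = sy[b] / vol[b]
            obz = sz[b] / vol[b]
            if b == cs:
                nbx, nby, nbz = ncsx, ncsy, ncsz
            elif b == ct:
                if nvt == 0:
                    dead_new = True
                    nbx, nby, nbz = obx, oby, obz
                else:
                    nbx, nby, nbz = nctx, ncty, nctz
            else:
                nbx, nby, nbz = obx, oby, obz
        else:
            obx, oby, obz = lax[li], lay[li], laz[li]
            nbx, nby, nbz = obx, oby, obz
        e_old = _pair_energy(lkind[li], llam[li], lL0[li], lsat[li],
                             oax, oay, oaz, obx, oby, obz)
        if dead_new:
            e_new = 0.0
        else:
            e_new = _pair_energy(lkind[li], llam[li], lL0[li], lsat[li],
                                 nax, nay, naz, nbx, nby, nbz)
        dE += e_new - e_old
    return dE


@njit(cache=True)
def delta_H(owner, J, ctype, vol, sx, sy, sz, lam_vol, v_target,
            lptr, lidx, lkind, la, lb, lax, lay, laz, llam, lL0, lsat,
            xt, yt, zt, o_s, o_t):
    """Energy change of copying owner ``o_s`` onto target voxel
    ``(xt, yt, zt)`` currently owned by ``o_t``."""
    X, Y, Z = owner.shape
    ts = _tcode(o_s, ctype)
    tt = _tcode(o_t, ctype)
    dE = 0.0
    # contact term over the 26-neighborhood of the target voxel
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                xn = xt + dx
                yn = yt + dy
                zn = zt + dz
                if xn < 0 or xn >= X or yn < 0 or yn >= Y \
                        or zn < 0 or zn >= Z:
                    continue
                on = owner[xn, yn, zn]
                if on != o_s:
                    dE += J[ts, _tcode(on, ctype)]
                if on != o_t:
                    dE -= J[tt, _tcode(on, ctype)]
    # volume-constraint term
    if o_s > 0:
        v = vol[o_s]
        dE += lam_vol * ((v + 1 - v_target) ** 2 - (v - v_target) ** 2)
    if o_t > 0:
        v = vol[o_t]
        dE += lam_vol * ((v - 1 - v_target) ** 2 - (v - v_target) ** 2)
    # link term via centroid shifts of the two affected cells
    ncsx = ncsy = ncsz = 0.0
    nvs = 0
    if o_s > 0:
        nvs = vol[o_s] + 1
        ncsx = (sx[o_s] + xt) / nvs
        ncsy = (sy[o_s] + yt) / nvs
        ncsz = (sz[o_s] + zt) / nvs
    nctx = ncty = nctz = 0.0
    nvt = -1
    if o_t > 0:
        nvt = vol[o_t] - 1
        if nvt > 0:
            nctx = (sx[o_t] - xt) / nvt
            ncty = (sy[o_t] - yt) / nvt
            nctz = (sz[o_t] - zt) / nvt
    cs = o_s if o_s > 0 else -1
    ct = o_t if o_t > 0 else -1
    if cs > 0:
        dE += _link_delta_for_cell(cs, cs, ct, -1,
                                   vol, sx, sy, sz,
                                   ncsx, ncsy, ncsz, nvs,
                                   nctx, ncty, nctz, nvt,
                                   lptr, lidx, lkind, la, lb,
                                   lax, lay, laz, llam, lL0, lsat)
    if ct > 0:
        dE += _link_delta_for_cell(ct, cs, ct, cs,
                                   vol, sx, sy, sz,
                                   ncsx, ncsy, ncsz, nvs,
                                   nctx, ncty, nctz, nvt,
                                   lptr, lidx, lkind, la, lb,
                                   lax, lay, laz, llam, lL0, lsat)
    return dE


@njit(cache=True)
def local_connectivity_ok(owner, xt, yt, zt, cid):
    """True if removing voxel (xt, yt, zt) from cell ``cid`` leaves its
    remaining voxels inside the 26-neighborhood in a single 26-connected
    component (the standard local fission guard; conservative).  An empty
    neighborhood (last voxel of the cell) is allowed: the cell dies."""
    X, Y, Z = owner.shape
    # collect neighborhood membership into a 3x3x3 mask
    mask = np.zeros(27, dtype=np.uint8)
    n_in = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                xn = xt + dx
                yn = yt + dy
                zn = zt + dz
                if xn < 0 or xn >= X or yn < 0 or yn >= Y \
                        or zn < 0 or zn >= Z:
                    continue
                if owner[xn, yn, zn] == cid:
                    mask[(dx + 1) * 9 + (dy + 1) * 3 + (dz + 1)] = 1
                    n_in += 1
    if n_in == 0:
        return True
    # BFS from the first member over 26-adjacency within the cube
    visited = np.zeros(27, dtype=np.uint8)
    queue = np.zeros(27, dtype=np.int64)
    start = -1
    for k in range(27):
        if mask[k] == 1:
            start = k
            break
    queue[0] = start
    visited[start] = 1
    head = 0
    tail = 1
    while head < tail:
        k = queue[head]
        head += 1
        kx = k // 9 - 1
        ky = (k // 3) % 3 - 1
        kz = k % 3 - 1
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    nx = kx + dx
                    ny = ky + dy
                    nz = kz + dz
                    if nx < -1 or nx > 1 or ny < -1 or ny > 1 \
                            or nz < -1 or nz > 1:
                        continue
                    kk = (nx + 1) * 9 + (ny + 1) * 3 + (nz + 1)
                    if mask[kk] == 1 and visited[kk] == 0:
                        visited[kk] = 1
                        queue[tail] = kk
                        tail += 1
    return tail == n_in


@njit(cache=True)
def run_sweep(owner, J, ctype, vol, sx, sy, sz, lam_vol, v_target, temp,
              lptr, lidx, lkind, la, lb, lax, lay, laz, llam, lL0, lsat,
              sites, dirs, unifs):
    """One Monte-Carlo step: ``len(sites)`` voxel-copy attempts.

    ``sites`` are flat indices over non-substrate lattice sites (z >= 1),
    ``dirs`` indexes the 6-neighborhood, ``unifs`` are uniform deviates
    for the Boltzmann acceptance.  Mutates owner/vol/sums in place and
    returns the number of accepted copies.
    """
    X, Y, Z = owner.shape
    zspan = Z - 1
    accepted = 0
    for i in range(sites.shape[0]):
        s = sites[i]
        x = s // (Y * zspan)
        rem = s % (Y * zspan)
        y = rem // zspan
        z = 1 + rem % zspan
        d = dirs[i]
        xn = x + _DX[d]
        yn = y + _DY[d]
        zn = z + _DZ[d]
        if xn < 0 or xn >= X or yn < 0 or yn >= Y or zn < 0 or zn >= Z:
            continue
        o_t = owner[xn, yn, zn]
        if o_t == _SUBSTRATE:
            continue
        o_s = owner[x, y, z]
        if o_s == o_t:
            continue
        dH = delta_H(owner, J, ctype, vol, sx, sy, sz, lam_vol, v_target,
                     lptr, lidx, lkind, la, lb, lax, lay, laz,
                     llam, lL0, lsat, xn, yn, zn, o_s, o_t)
        if dH <= 0.0 or unifs[i] < np.exp(-dH / temp):
            # fission guard, applied to otherwise-accepted copies only
            if o_t > 0 and not local_connectivity_ok(owner, xn, yn, zn, o_t):
                continue
            owner[xn, yn, zn] = o_s
            if o_s > 0:
                vol[o_s] += 1
                sx[o_s] += xn
                sy[o_s] += yn
                sz[o_s] += zn
            if o_t > 0:
                vol[o_t] -= 1
                sx[o_t] -= xn
                sy[o_t] -= yn
                sz[o_t] -= zn
            accepted += 1
    return accepted
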