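"""Numba kernels for the DPD engine.

All kernels operate on flat numpy arrays in reduced units (r_c = 1, m = 1,
kT = 1).  The pairwise random force uses a counter-based construction: the
per-pair noise variate is a pure hash of (seed, step, i, j) with i < j, so
theta_ij == theta_ji exactly and a run is reproducible independently of the
iteration order of the pair loop, and a restarted run continues the same
noise stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT3 = np.sqrt(3.0)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_noise(hstep, i, j):
    """Symmetric unit-variance variate for pair (i, j) at a given step.

    ``hstep`` is the precomputed hash of (seed, step).  Uniform on
    [-sqrt(3), sqrt(3)] (variance 1), the conventional cheap DPD noise;
    keyed on ordered (i, j) so swapping partners gives the identical value.
    """
    if i > j:
        i, j = j, i
    key = (np.uint64(i) << np.uint64(32)) | np.uint64(j)
    h = _splitmix64(np.uint64(hstep) ^ key)
    u = np.float64(h >> np.uint64(11)) * _INV_2_53
    return _SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, inline="always")
def step_hash(seed, step):
    return _splitmix64(np.uint64(seed) ^ _splitmix64(np.uint64(step)))


@njit(cache=True)
def _cell_index(pos, box, ncell, cid):
    n = pos.shape[0]
    for k in range(n):
        ix = np.int64(pos[k, 0] / box[0] * ncell[0])
        iy = np.int64(pos[k, 1] / box[1] * ncell[1])
        iz = np.int64(pos[k, 2] / box[2] * ncell[2])
        # guard against coordinates exactly at the upper box edge
        if ix >= ncell[0]:
            ix = ncell[0] - 1
        if iy >= ncell[1]:
            iy = ncell[1] - 1
        if iz >= ncell[2]:
            iz = ncell[2] - 1
        cid[k] = (iz * ncell[1] + iy) * ncell[0] + ix


@njit(cache=True)
def _counting_sort(cid, ntot_cells):
    n = cid.shape[0]
    start = np.zeros(ntot_cells + 1, dtype=np.int64)
    for k in range(n):
        start[cid[k] + 1] += 1
    for c in range(ntot_cells):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for k in range(n):
        c = cid[k]
        order[fill[c]] = k
        fill[c] += 1
    return start, order


# half-shell of 13 neighbour cell offsets plus the self cell handled separately
_HALF_OFFSETS = np.array(
    [
        (1, 0, 0),
        (0, 1, 0), (1, 1, 0), (-1, 1, 0),
        (0, 0, 1), (1, 0, 1), (-1, 0, 1),
        (0, 1, 1), (1, 1, 1), (-1, 1, 1),
        (0, -1, 1), (1, -1, 1), (-1, -1, 1),
    ],
    dtype=np.int64,
)


@njit(cache=True, fastmath=True, inline="always")
def _accumulate_pair(dx, dy, dz, p, q, gi, gj, ti, tj, svel, aij, gamma,
                     sigma_isqdt, hstep, fmax, sforce):
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= 1.0 or r2 <= 1e-24:
        return 0.0, 0.0, 0.0
    r = np.sqrt(r2)
    w = 1.0 - r
    inv_r = 1.0 / r
    ex = dx * inv_r
    ey = dy * inv_r
    ez = dz * inv_r
    rv = (ex * (svel[p, 0] - svel[q, 0])
          + ey * (svel[p, 1] - svel[q, 1])
          + ez * (svel[p, 2] - svel[q, 2]))
    f = aij[ti, tj] * w
    f -= gamma * w * w * rv
    f += sigma_isqdt * w * _pair_noise(hstep, gi, gj)
    if fmax > 0.0:
        if f > fmax:
            f = fmax
        elif f < -fmax:
            f = -fmax
    fx = f * ex
    fy = f * ey
    fz = f * ez
    sforce[q, 0] -= fx
    sforce[q, 1] -= fy
    sforce[q, 2] -= fz
    return fx, fy, fz


def make_workspace(n: int, box: np.ndarray) -> tuple:
    """Scratch arrays for :func:`nonbonded_forces` (reused across steps)."""
    ncx = max(int(box[0]), 1)
    ncy = max(int(box[1]), 1)
    ncol = ncx * ncy
    return (
        np.empty((n, 3)),                 # spos
        np.empty((n, 3)),                 # svel
        np.empty(n, dtype=np.int64),      # stypes
        np.empty((n, 3)),                 # sforce
        np.empty(n, dtype=np.int64),      # cid
        np.empty(n, dtype=np.int64),      # order
        np.empty(ncol + 1, dtype=np.int64),  # start
    )


# half set of neighbour column offsets in the xy plane (plus the self column)
_COL_OFFSETS = np.array(
    [(1, 0), (0, 1), (1, 1), (1, -1)],
    dtype=np.int64,
)


@njit(cache=True, fastmath=True)
def nonbonded_forces(pos, vel, types, aij, gamma, sigma, isqdt,
                     box, seed, step, fmax, forces,
                     spos, svel, stypes, sforce, cid, order, start):
    """Accumulate conservative + dissipative + random pair forces.

    Pair search uses sorted columns: the xy plane is divided into 1 r_c
    columns, particles are sorted by z within each column, and each particle
    is tested against the z-window [z - r_c, z + r_c) of its own and four
    half-shell neighbour columns (sliding-window pointers; wrapped z-window
    segments handled at the column ends).  Falls back to the all-pairs loop
    when any box side is below 3 r_c.  ``fmax`` > 0 clamps the per-pair
    scalar force (capped-force pre-equilibration); <= 0 disables it.

    The trailing arguments are caller-owned scratch arrays (see
    :func:`make_workspace`), reused across steps to avoid per-call
    allocation.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    hstep = step_hash(seed, step)
    sigma_isqdt = sigma * isqdt
    ncx = max(np.int64(lx), 1)
    ncy = max(np.int64(ly), 1)
    if ncx < 3 or ncy < 3 or lz < 3.0:
        hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx > hx:
                    dx -= lx
                elif dx < -hx:
                    dx += lx
                if dy > hy:
                    dy -= ly
                elif dy < -hy:
                    dy += ly
                if dz > hz:
                    dz -= lz
                elif dz < -hz:
                    dz += lz
                fx, fy, fz = _accumulate_pair(
                    dx, dy, dz, i, j, i, j, types[i], types[j], vel, aij,
                    gamma, sigma_isqdt, hstep, fmax, forces)
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
        return

    ncol = ncx * ncy
    for k in range(n):
        ix = np.int64(pos[k, 0] / lx * ncx)
        iy = np.int64(pos[k, 1] / ly * ncy)
        if ix >= ncx:
            ix = ncx - 1
        if iy >= ncy:
            iy = ncy - 1
        cid[k] = iy * ncx + ix
    # counting sort into the caller's order/start scratch
    for c in range(ncol + 1):
        start[c] = 0
    for k in range(n):
        start[cid[k] + 1] += 1
    for c in range(ncol):
        start[c + 1] += start[c]
    for k in range(n):
        c = cid[k]
        order[start[c]] = k
        start[c] += 1
    for c in range(ncol, 0, -1):
        start[c] = start[c - 1]
    start[0] = 0

    # z-sort each column (insertion sort on the order slice)
    for c in range(ncol):
        a0 = start[c]
        a1 = start[c + 1]
        for p in range(a0 + 1, a1):
            k = order[p]
            zk = pos[k, 2]
            q = p - 1
            while q >= a0 and pos[order[q], 2] > zk:
                order[q + 1] = order[q]
                q -= 1
            order[q + 1] = k

    # gather into sorted order
    for p in range(n):
        k = order[p]
        spos[p, 0] = pos[k, 0]
        spos[p, 1] = pos[k, 1]
        spos[p, 2] = pos[k, 2]
        svel[p, 0] = vel[k, 0]
        svel[p, 1] = vel[k, 1]
        svel[p, 2] = vel[k, 2]
        stypes[p] = types[k]
        sforce[p, 0] = 0.0
        sforce[p, 1] = 0.0
        sforce[p, 2] = 0.0

    for cy in range(ncy):
        for cx in range(ncx):
            c = cy * ncx + cx
            a0 = start[c]
            a1 = start[c + 1]
            if a0 == a1:
                continue
            # self column: ascending z, forward window only
            for p in range(a0, a1):
                xi = spos[p, 0]
                yi = spos[p, 1]
                zi = spos[p, 2]
                ti = stypes[p]
                gi = order[p]
                fxi = 0.0
                fyi = 0.0
                fzi = 0.0
                for q in range(p + 1, a1):
                    dz = zi - spos[q, 2]
                    if dz <= -1.0:
                        break
                    fx, fy, fz = _accumulate_pair(
                        xi - spos[q, 0], yi - spos[q, 1], dz,
                        p, q, gi, order[q], ti, stypes[q], svel, aij,
                        gamma, sigma_isqdt, hstep, fmax, sforce)
                    fxi += fx
                    fyi += fy
                    fzi += fz
                # z-wrapped partners: high-z p with low-z q
                if zi > lz - 1.0:
                    for q in range(a0, a1):
                        dz = zi - spos[q, 2] - lz
                        if dz <= -1.0:
                            break
                        if q != p and dz < 1.0:
                            fx, fy, fz = _accumulate_pair(
                                xi - spos[q, 0], yi - spos[q, 1], dz,
                                p, q, gi, order[q], ti, stypes[q], svel, aij,
                                gamma, sigma_isqdt, hstep, fmax, sforce)
                            fxi += fx
                            fyi += fy
                            fzi += fz
                sforce[p, 0] += fxi
                sforce[p, 1] += fyi
                sforce[p, 2] += fzi
            # four half-shell neighbour columns
            for o in range(4):
                nx = cx + _COL_OFFSETS[o, 0]
                sx = 0.0
                if nx < 0:
                    nx += ncx
                    sx = lx
                elif nx >= ncx:
                    nx -= ncx
                    sx = -lx
                ny = cy + _COL_OFFSETS[o, 1]
                sy = 0.0
                if ny < 0:
                    ny += ncy
                    sy = ly
                elif ny >= ncy:
                    ny -= ncy
                    sy = -ly
                c2 = ny * ncx + nx
                b0 = start[c2]
                b1 = start[c2 + 1]
                if b0 == b1:
                    continue
                lo = b0
                hi = b0
                for p in range(a0, a1):
                    xi = spos[p, 0] + sx
                    yi = spos[p, 1] + sy
                    zi = spos[p, 2]
                    ti = stypes[p]
                    gi = order[p]
                    fxi = 0.0
                    fyi = 0.0
                    fzi = 0.0
                    while lo < b1 and spos[lo, 2] <= zi - 1.0:
                        lo += 1
                    while hi < b1 and spos[hi, 2] < zi + 1.0:
                        hi += 1
                    for q in range(lo, hi):
                        fx, fy, fz = _accumulate_pair(
                            xi - spos[q, 0], yi - spos[q, 1], zi - spos[q, 2],
                            p, q, gi, order[q], ti, stypes[q], svel, aij,
                            gamma, sigma_isqdt, hstep, fmax, sforce)
                        fxi += fx
                        fyi += fy
                        fzi += fz
                    # z-wrapped window segments at the column ends
                    if zi < 1.0:
                        for q in range(b1 - 1, b0 - 1, -1):
                            dz = zi - spos[q, 2] + lz
                            if dz >= 1.0:
                                break
                            fx, fy, fz = _accumulate_pair(
                                xi - spos[q, 0], yi - spos[q, 1], dz,
                                p, q, gi, order[q], ti, stypes[q], svel, aij,
                                gamma, sigma_isqdt, hstep, fmax, sforce)
                            fxi += fx
                            fyi += fy
                            fzi += fz
                    elif zi > lz - 1.0:
                        for q in range(b0, b1):
                            dz = zi - spos[q, 2] - lz
                            if dz <= -1.0:
                                break
                            fx, fy, fz = _accumulate_pair(
                                xi - spos[q, 0], yi - spos[q, 1], dz,
                                p, q, gi, order[q], ti, stypes[q], svel, aij,
                                gamma, sigma_isqdt, hstep, fmax, sforce)
                            fxi += fx
                            fyi += fy
                            fzi += fz
                    sforce[p, 0] += fxi
                    sforce[p, 1] += fyi
                    sforce[p, 2] += fzi

    # scatter back to original order
    for p in range(n):
        k = order[p]
        forces[k, 0] += sforce[p, 0]
        forces[k, 1] += sforce[p, 1]
        forces[k, 2] += sforce[p, 2]


@njit(cache=True, fastmath=True)
def bond_forces(pos, bonds, k_spring, r0, box, forces):
    """Harmonic bond forces -k (r - r0) r_hat, minimum image."""
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= 1e-12:
            continue
        f = -k_spring * (r - r0) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz


@njit(cache=True)
def neighbor_pairs_kernel(pos, box):
    """Index pairs (i < j) with minimum-image distance < r_c = 1.

    Cell list when the box admits it, all-pairs otherwise; the returned set
    is identical either way.
    """
    n = pos.shape[0]
    ncell = np.empty(3, dtype=np.int64)
    for d in range(3):
        ncell[d] = np.int64(box[d])
        if ncell[d] < 1:
            ncell[d] = 1
    cap = 64 + n * 32
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    if ncell[0] < 3 or ncell[1] < 3 or ncell[2] < 3:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.rint(dx / box[0])
                dy -= box[1] * np.rint(dy / box[1])
                dz -= box[2] * np.rint(dz / box[2])
                if dx * dx + dy * dy + dz * dz < 1.0:
                    if m >= cap:
                        tmp = np.empty((cap * 2, 2), dtype=np.int64)
                        tmp[:m] = out[:m]
                        out = tmp
                        cap *= 2
                    out[m, 0] = min(i, j)
                    out[m, 1] = max(i, j)
                    m += 1
        return out[:m]

    ntot = ncell[0] * ncell[1] * ncell[2]
    cid = np.empty(n, dtype=np.int64)
    _cell_index(pos, box, ncell, cid)
    start, order = _counting_sort(cid, ntot)
    for cz in range(ncell[2]):
        for cy in range(ncell[1]):
            for cx in range(ncell[0]):
                c = (cz * ncell[1] + cy) * ncell[0] + cx
                a0 = start[c]
                a1 = start[c + 1]
                for o in range(14):
                    if o == 0:
                        c2 = c
                        b0 = a0
                        b1 = a1
                    else:
                        nx = (cx + _HALF_OFFSETS[o - 1, 0]) % ncell[0]
                        ny = (cy + _HALF_OFFSETS[o - 1, 1]) % ncell[1]
                        nz = (cz + _HALF_OFFSETS[o - 1, 2]) % ncell[2]
                        c2 = (nz * ncell[1] + ny) * ncell[0] + nx
                        b0 = start[c2]
                        b1 = start[c2 + 1]
                    for p in range(a0, a1):
                        i = order[p]
                        qlo = p + 1 if o == 0 else b0
                        for q in range(qlo, b1):
                            j = order[q]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box[0] * np.rint(dx / box[0])
                            dy -= box[1] * np.rint(dy / box[1])
                            dz -= box[2] * np.rint(dz / box[2])
                            if dx * dx + dy * dy + dz * dz < 1.0:
                                if m >= cap:
                                    tmp = np.empty((cap * 2, 2), dtype=np.int64)
                                    tmp[:m] = out[:m]
                                    out = tmp
                                    cap *= 2
                                out[m, 0] = min(i, j)
                                out[m, 1] = max(i, j)
                                m += 1
    return out[:m]


@njit(cache=True)
def unwrap_by_parent(pos, parent, box, out):
    """Unwrap molecules across periodic boundaries.

    ``parent[k]`` is the bead that bead k is bonded to with parent[k] < k,
    or -1 for the first bead of a molecule.  A single index-ordered pass
    places every bead at its parent's unwrapped position plus the
    minimum-image bond vector.
    """
    n = pos.shape[0]
    for k in range(n):
        p = parent[k]
        if p < 0:
            out[k, 0] = pos[k, 0]
            out[k, 1] = pos[k, 1]
            out[k, 2] = pos[k, 2]
        else:
            for d in range(3):
                dxd = pos[k, d] - pos[p, d]
                dxd -= box[d] * np.rint(dxd / box[d])
                out[k, d] = out[p, d] + dxd


@njit(cache=True, fastmath=True)
def wrap_positions(pos, box):
    n = pos.shape[0]
    for k in range(n):
        for d in range(3):
            x = pos[k, d]
            x -= box[d] * np.floor(x / box[d])
            if x >= box[d]:
                x -= box[d]
            if x < 0.0:
                x = 0.0
            pos[k, d] = x


@njit(cache=True, fastmath=True)
def advance_positions(pos, vel, forces, dt, box):
    """x += dt v + dt^2/2 f, wrapped into [0, L), in one fused pass."""
    half = 0.5 * dt * dt
    for k in range(pos.shape[0]):
        for d in range(3):
            x = pos[k, d] + dt * vel[k, d] + half * forces[k, d]
            x -= box[d] * np.floor(x / box[d])
            if x >= box[d]:
                x -= box[d]
            if x < 0.0:
                x = 0.0
            pos[k, d] = x
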