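"""Numba kernels: cell-list pair forces, bonded forces, stress binning.

Design notes
------------
* Minimum-image convention on all three periodic axes everywhere.
* The random pair force uses a counter-based RNG: each (step, pair) gets a
  zero-mean unit-variance Gaussian derived from a splitmix64 hash of
  (noise key, sorted pair indices) via Box-Muller.  The draw is symmetric
  (zeta_ij == zeta_ji) and independent of the traversal order, so the
  cell-list and all-pairs paths produce identical noise and trajectories
  are bitwise reproducible for a given seed.
* The half-stencil cell loop requires at least 3 cells per axis; callers
  fall back to the all-pairs kernel for smaller boxes.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_M1 = U64(0xBF58476D1CE4E5B9)
_SM_M2 = U64(0x94D049BB133111EB)
_INV53 = 1.1102230246251565e-16  # 2**-53
_TWO_PI = 6.283185307179586

# 13 half-stencil neighbour offsets (each unordered cell pair visited once)
_OFFSETS = np.array(
    [(dx, dy, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    + [(dx, 1, 0) for dx in (-1, 0, 1)]
    + [(1, 0, 0)],
    dtype=np.int64,
)


@njit(inline="always", fastmath=True)
def _mix(x):
    x = x + _SM_GAMMA
    z = x
    z = (z ^ (z >> U64(30))) * _SM_M1
    z = (z ^ (z >> U64(27))) * _SM_M2
    return z ^ (z >> U64(31))


@njit(inline="always", fastmath=True)
def _pair_gauss(key, i, j):
    """One Gaussian draw shared by the (i, j) pair; i < j assumed."""
    a = _mix(key ^ (U64(i) * _SM_M1))
    b = _mix(a ^ (U64(j) * _SM_M2))
    c = _mix(b)
    u1 = float(b >> U64(11)) * _INV53 + 1e-18
    u2 = float(c >> U64(11)) * _INV53
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(_TWO_PI * u2)


@njit(inline="always")
def _minimg(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(inline="always")
def _pair_interact(i, j, pos, vel, species, amat, L, rcut, gamma, sigma,
                   inv_sqrt_dt, key, forces):
    """DPD conservative + dissipative + random force for one pair.

    Returns (pair potential energy, overlap flag)."""
    dx = _minimg(pos[i, 0] - pos[j, 0], L)
    dy = _minimg(pos[i, 1] - pos[j, 1], L)
    dz = _minimg(pos[i, 2] - pos[j, 2], L)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rcut * rcut:
        return 0.0, 0
    a = amat[species[i], species[j]]
    ii = i if i < j else j
    jj = j if i < j else i
    if r2 < 1e-24:
        u = _overlap_kick(i, j, a, sigma, inv_sqrt_dt, rcut, key, forces)
        return u, 1
    r = math.sqrt(r2)
    w = 1.0 - r / rcut
    vdot = ((vel[i, 0] - vel[j, 0]) * dx + (vel[i, 1] - vel[j, 1]) * dy
            + (vel[i, 2] - vel[j, 2]) * dz)
    zeta = _pair_gauss(key, ii, jj)
    fm = a * w - gamma * w * w * (vdot / r) + sigma * w * zeta * inv_sqrt_dt
    fx = fm * dx / r
    fy = fm * dy / r
    fz = fm * dz / r
    forces[i, 0] += fx
    forces[i, 1] += fy
    forces[i, 2] += fz
    forces[j, 0] -= fx
    forces[j, 1] -= fy
    forces[j, 2] -= fz
    return 0.5 * a * rcut * w * w, 0


@njit
def build_cells(pos, L, M):
    """Counting-sort cell list: returns (cell_start, order)."""
    N = pos.shape[0]
    width = L / M
    cell = np.empty(N, np.int64)
    for i in range(N):
        ix = int(pos[i, 0] / width)
        iy = int(pos[i, 1] / width)
        iz = int(pos[i, 2] / width)
        if ix >= M:
            ix = M - 1
        if iy >= M:
            iy = M - 1
        if iz >= M:
            iz = M - 1
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        cell[i] = (iz * M + iy) * M + ix
    ncell = M * M * M
    start = np.zeros(ncell + 1, np.int64)
    for i in range(N):
        start[cell[i] + 1] += 1
    for c in range(1, ncell + 1):
        start[c] += start[c - 1]
    order = np.empty(N, np.int64)
    fill = start[:ncell].copy()
    for i in range(N):
        order[fill[cell[i]]] = i
        fill[cell[i]] += 1
    return start, order


@njit(inline="always", fastmath=True)
def _overlap_kick(i, j, a, sigma, inv_sqrt_dt, rcut, key, forces):
    """Exactly overlapping pair: contact-value magnitude, random direction."""
    ii = i if i < j else j
    jj = j if i < j else i
    k0 = _mix(key ^ (U64(ii) * _SM_M2) ^ (U64(jj) * _SM_M1))
    ex = _pair_gauss(k0, ii, jj)
    ey = _pair_gauss(k0 + U64(1), ii, jj)
    ez = _pair_gauss(k0 + U64(2), ii, jj)
    en = math.sqrt(ex * ex + ey * ey + ez * ez) + 1e-300
    zeta = _pair_gauss(key, ii, jj)
    fm = (a + sigma * zeta * inv_sqrt_dt) / en
    forces[ii, 0] += fm * ex
    forces[ii, 1] += fm * ey
    forces[ii, 2] += fm * ez
    forces[jj, 0] -= fm * ex
    forces[jj, 1] -= fm * ey
    forces[jj, 2] -= fm * ez
    return 0.5 * a * rcut


@njit(fastmath=True)
def pair_forces_cells(pos, vel, species, amat, L, rcut, gamma, sigma,
                      inv_sqrt_dt, key, M, cell_start, order, offsets, forces):
    U = 0.0
    n_overlap = 0
    rc2 = rcut * rcut
    for cz in range(M):
        for cy in range(M):
            for cx in range(M):
                c = (cz * M + cy) * M + cx
                s0 = cell_start[c]
                e0 = cell_start[c + 1]
                for p in range(s0, e0):
                    i = order[p]
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    zi = pos[i, 2]
                    for q in range(p + 1, e0):
                        j = order[q]
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2:
                            if r2 > 1e-24:
                                r = math.sqrt(r2)
                                w = 1.0 - r / rcut
                                a = amat[species[i], species[j]]
                                vd = ((vel[i, 0] - vel[j, 0]) * dx
                                      + (vel[i, 1] - vel[j, 1]) * dy
                                      + (vel[i, 2] - vel[j, 2]) * dz)
                                ii = i if i < j else j
                                jj = j if i < j else i
                                zeta = _pair_gauss(key, ii, jj)
                                fm = (a * w - gamma * w * w * (vd / r)
                                      + sigma * w * zeta * inv_sqrt_dt)
                                fx = fm * dx / r
                                fy = fm * dy / r
                                fz = fm * dz / r
                                forces[i, 0] += fx
                                forces[i, 1] += fy
                                forces[i, 2] += fz
                                forces[j, 0] -= fx
                                forces[j, 1] -= fy
                                forces[j, 2] -= fz
                                U += 0.5 * a * rcut * w * w
                            else:
                                a = amat[species[i], species[j]]
                                U += _overlap_kick(i, j, a, sigma,
                                                   inv_sqrt_dt, rcut, key,
                                                   forces)
                                n_overlap += 1
                # half stencil; explicit image shifts (cell width >= rcut)
                for k in range(offsets.shape[0]):
                    ox = cx + offsets[k, 0]
                    oy = cy + offsets[k, 1]
                    oz = cz + offsets[k, 2]
                    sx = 0.0
                    sy = 0.0
                    sz = 0.0
                    if ox < 0:
                        ox += M
                        sx = -L
                    elif ox >= M:
                        ox -= M
                        sx = L
                    if oy < 0:
                        oy += M
                        sy = -L
                    elif oy >= M:
                        oy -= M
                        sy = L
                    if oz < 0:
                        oz += M
                        sz = -L
                    elif oz >= M:
                        oz -= M
                        sz = L
                    d = (oz * M + oy) * M + ox
                    s1 = cell_start[d]
                    e1 = cell_start[d + 1]
                    for p in range(s0, e0):
                        i = order[p]
                        xi = pos[i, 0] - sx
                        yi = pos[i, 1] - sy
                        zi = pos[i, 2] - sz
                        for q in range(s1, e1):
                            j = order[q]
                            dx = xi - pos[j, 0]
                            dy = yi - pos[j, 1]
                            dz = zi - pos[j, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2:
                                if r2 > 1e-24:
                                    r = math.sqrt(r2)
                                    w = 1.0 - r / rcut
                                    a = amat[species[i], species[j]]
                                    vd = ((vel[i, 0] - vel[j, 0]) * dx
                                          + (vel[i, 1] - vel[j, 1]) * dy
                                          + (vel[i, 2] - vel[j, 2]) * dz)
                                    ii = i if i < j else j
                                    jj = j if i < j else i
                                    zeta = _pair_gauss(key, ii, jj)
                                    fm = (a * w - gamma * w * w * (vd / r)
                                          + sigma * w * zeta * inv_sqrt_dt)
                                    fx = fm * dx / r
                                    fy = fm * dy / r
                                    fz = fm * dz / r
                                    forces[i, 0] += fx
                                    forces[i, 1] += fy
                                    forces[i, 2] += fz
                                    forces[j, 0] -= fx
                                    forces[j, 1] -= fy
                                    forces[j, 2] -= fz
                                    U += 0.5 * a * rcut * w * w
                                else:
                                    a = amat[species[i], species[j]]
                                    U += _overlap_kick(i, j, a, sigma,
                                                       inv_sqrt_dt, rcut,
                                                       key, forces)
                                    n_overlap += 1
    return U, n_overlap


@njit
def pair_forces_allpairs(pos, vel, species, amat, L, rcut, gamma, sigma,
                         inv_sqrt_dt, key, forces):
    U = 0.0
    n_overlap = 0
    N = pos.shape[0]
    for i in range(N - 1):
        for j in range(i + 1, N):
            u, o = _pair_interact(i, j, pos, vel, species, amat, L, rcut,
                                  gamma, sigma, inv_sqrt_dt, key, forces)
            U += u
            n_overlap += o
    return U, n_overlap


@njit(inline="always")
def _angle_g(kth, t0, th, s):
    """Robust dU/dtheta / sin(theta) for U = k (theta - theta0)^2.

    Near the collinear limits the ratio (theta - theta0)/sin(theta) is
    evaluated by series when theta0 sits at the same limit; otherwise the
    sine is clamped (genuinely singular configuration).  Returns
    (g, clamped_flag).
    """
    if s > 1e-4:
        return 2.0 * kth * (th - t0) / s, 0
    if th > math.pi - 1e-4 and abs(t0 - math.pi) < 1e-12:
        u0 = math.pi - th
        return -2.0 * kth * (1.0 + u0 * u0 / 6.0), 0
    if th < 1e-4 and t0 < 1e-12:
        return 2.0 * kth * (1.0 + th * th / 6.0), 0
    return 2.0 * kth * (th - t0) / 1e-4, 1


@njit
def bonded_forces_kernel(pos, L, bond_idx, bond_ks, bond_rs, angle_idx,
                         angle_k, angle_t0, forces):
    """Harmonic bond U = (k_s/2)(r - r_s)^2 and bending U = k_th (th - th0)^2.

    Returns (bond energy, angle energy, number of clamped angle gradients)."""
    eb = 0.0
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = _minimg(pos[i, 0] - pos[j, 0], L)
        dy = _minimg(pos[i, 1] - pos[j, 1], L)
        dz = _minimg(pos[i, 2] - pos[j, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_rs[b]
        eb += 0.5 * bond_ks[b] * dr * dr
        if r > 1e-300:
            fm = -bond_ks[b] * dr / r
            forces[i, 0] += fm * dx
            forces[i, 1] += fm * dy
            forces[i, 2] += fm * dz
            forces[j, 0] -= fm * dx
            forces[j, 1] -= fm * dy
            forces[j, 2] -= fm * dz
    ea = 0.0
    n_clamped = 0
    for t in range(angle_idx.shape[0]):
        i = angle_idx[t, 0]
        j = angle_idx[t, 1]  # apex
        k = angle_idx[t, 2]
        ux = _minimg(pos[i, 0] - pos[j, 0], L)
        uy = _minimg(pos[i, 1] - pos[j, 1], L)
        uz = _minimg(pos[i, 2] - pos[j, 2], L)
        vx = _minimg(pos[k, 0] - pos[j, 0], L)
        vy = _minimg(pos[k, 1] - pos[j, 1], L)
        vz = _minimg(pos[k, 2] - pos[j, 2], L)
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        th = math.acos(c)
        s = math.sqrt(max(1.0 - c * c, 0.0))
        kth = angle_k[t]
        t0 = angle_t0[t]
        ea += kth * (th - t0) * (th - t0)
        g, cl = _angle_g(kth, t0, th, s)
        n_clamped += cl
        fix = g * (vx / (ru * rv) - c * ux / (ru * ru))
        fiy = g * (vy / (ru * rv) - c * uy / (ru * ru))
        fiz = g * (vz / (ru * rv) - c * uz / (ru * ru))
        fkx = g * (ux / (ru * rv) - c * vx / (rv * rv))
        fky = g * (uy / (ru * rv) - c * vy / (rv * rv))
        fkz = g * (uz / (ru * rv) - c * vz / (rv * rv))
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return eb, ea, n_clamped


# ---------------------------------------------------------------------------
# Irving-Kirkwood stress binning (conservative + bonded contributions)
# ---------------------------------------------------------------------------

@njit(inline="always")
def _distribute(z0, z1, L, nbins, wx, wy, wz, si, sj, out):
    """Distribute a pair virial (wx, wy, wz) over slabs crossed by the
    axis-coordinate segment [z0, z1], in proportion to path length (IK-1
    contour); half of the weight goes to each endpoint's species channel."""
    if z1 < z0:
        tmp = z0
        z0 = z1
        z1 = tmp
    h = L / nbins
    total = z1 - z0
    if total < 1e-12:
        b = int((z0 - L * math.floor(z0 / L)) / h)
        if b >= nbins:
            b = nbins - 1
        out[b, 0, si] += 0.5 * wx
        out[b, 0, sj] += 0.5 * wx
        out[b, 1, si] += 0.5 * wy
        out[b, 1, sj] += 0.5 * wy
        out[b, 2, si] += 0.5 * wz
        out[b, 2, sj] += 0.5 * wz
        return
    k0 = int(math.floor(z0 / h))
    k1 = int(math.floor(z1 / h))
    for k in range(k0, k1 + 1):
        lo = max(z0, k * h)
        hi = min(z1, (k + 1) * h)
        if hi <= lo:
            continue
        b = k % nbins
        f = (hi - lo) / total
        out[b, 0, si] += 0.5 * f * wx
        out[b, 0, sj] += 0.5 * f * wx
        out[b, 1, si] += 0.5 * f * wy
        out[b, 1, sj] += 0.5 * f * wy
        out[b, 2, si] += 0.5 * f * wz
        out[b, 2, sj] += 0.5 * f * wz


@njit(inline="always")
def _stress_pair(i, j, pos, species, amat, L, rcut, axis, nbins, out, glob):
    dx = _minimg(pos[i, 0] - pos[j, 0], L)
    dy = _minimg(pos[i, 1] - pos[j, 1], L)
    dz = _minimg(pos[i, 2] - pos[j, 2], L)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rcut * rcut or r2 < 1e-24:
        return
    r = math.sqrt(r2)
    w = 1.0 - r / rcut
    a = amat[species[i], species[j]]
    fr = a * w / r  # F_ij = fr * d (force on i)
    wx = fr * dx * dx
    wy = fr * dy * dy
    wz = fr * dz * dz
    glob[0] += wx
    glob[1] += wy
    glob[2] += wz
    if axis == 0:
        z0 = pos[i, 0]
        da = dx
    elif axis == 1:
        z0 = pos[i, 1]
        da = dy
    else:
        z0 = pos[i, 2]
        da = dz
    _distribute(z0, z0 - da, L, nbins, wx, wy, wz, species[i], species[j], out)


@njit
def ik_pair_stress_cells(pos, species, amat, L, rcut, axis, nbins, M,
                         cell_start, order, offsets, out, glob):
    """Conservative-pair virial, slab-resolved along `axis` plus global sum."""
    for cz in range(M):
        for cy in range(M):
            for cx in range(M):
                c = (cz * M + cy) * M + cx
                s0 = cell_start[c]
                e0 = cell_start[c + 1]
                for p in range(s0, e0):
                    i = order[p]
                    for q in range(p + 1, e0):
                        _stress_pair(i, order[q], pos, species, amat, L, rcut,
                                     axis, nbins, out, glob)
                for k in range(offsets.shape[0]):
                    nx = (cx + offsets[k, 0]) % M
                    ny = (cy + offsets[k, 1]) % M
                    nz = (cz + offsets[k, 2]) % M
                    d = (nz * M + ny) * M + nx
                    for p in range(s0, e0):
                        i = order[p]
                        for q in range(cell_start[d], cell_start[d + 1]):
                            _stress_pair(i, order[q], pos, species, amat, L,
                                         rcut, axis, nbins, out, glob)


@njit
def ik_pair_stress_allpairs(pos, species, amat, L, rcut, axis, nbins, out,
                            glob):
    N = pos.shape[0]
    for i in range(N - 1):
        for j in range(i + 1, N):
            _stress_pair(i, j, pos, species, amat, L, rcut, axis, nbins, out,
                         glob)


@njit(inline="always")
def _stress_segment(i, j, fx, fy, fz, dx, dy, dz, pos, species, axis, L,
                    nbins, out, glob):
    """Add one bonded 'arm' contribution F_i . d (d = r_i - r_j, min image)."""
    wx = fx * dx
    wy = fy * dy
    wz = fz * dz
    glob[0] += wx
    glob[1] += wy
    glob[2] += wz
    if axis == 0:
        z0 = pos[i, 0]
        da = dx
    elif axis == 1:
        z0 = pos[i, 1]
        da = dy
    else:
        z0 = pos[i, 2]
        da = dz
    _distribute(z0, z0 - da, L, nbins, wx, wy, wz, species[i], species[j], out)


@njit
def ik_bonded_stress(pos, species, L, bond_idx, bond_ks, bond_rs, angle_idx,
                     angle_k, angle_t0, axis, nbins, out, glob):
    """Bond and angle virial, slab-resolved.  Angle (three-body) terms are
    decomposed into two pairwise arms i-apex and k-apex, which preserves the
    total virial because the apex force is minus the sum of the other two."""
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = _minimg(pos[i, 0] - pos[j, 0], L)
        dy = _minimg(pos[i, 1] - pos[j, 1], L)
        dz = _minimg(pos[i, 2] - pos[j, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-300:
            continue
        fm = -bond_ks[b] * (r - bond_rs[b]) / r
        _stress_segment(i, j, fm * dx, fm * dy, fm * dz, dx, dy, dz, pos,
                        species, axis, L, nbins, out, glob)
    for t in range(angle_idx.shape[0]):
        i = angle_idx[t, 0]
        j = angle_idx[t, 1]
        k = angle_idx[t, 2]
        ux = _minimg(pos[i, 0] - pos[j, 0], L)
        uy = _minimg(pos[i, 1] - pos[j, 1], L)
        uz = _minimg(pos[i, 2] - pos[j, 2], L)
        vx = _minimg(pos[k, 0] - pos[j, 0], L)
        vy = _minimg(pos[k, 1] - pos[j, 1], L)
        vz = _minimg(pos[k, 2] - pos[j, 2], L)
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        th = math.acos(c)
        s = math.sqrt(max(1.0 - c * c, 0.0))
        g, _cl = _angle_g(angle_k[t], angle_t0[t], th, s)
        fix = g * (vx / (ru * rv) - c * ux / (ru * ru))
        fiy = g * (vy / (ru * rv) - c * uy / (ru * ru))
        fiz = g * (vz / (ru * rv) - c * uz / (ru * ru))
        fkx = g * (ux / (ru * rv) - c * vx / (rv * rv))
        fky = g * (uy / (ru * rv) - c * vy / (rv * rv))
        fkz = g * (uz / (ru * rv) - c * vz / (rv * rv))
        _stress_segment(i, j, fix, fiy, fiz, ux, uy, uz, pos, species, axis,
                        L, nbins, out, glob)
        _stress_segment(k, j, fkx, fky, fkz, vx, vy, vz, pos, species, axis,
                        L, nbins, out, glob)
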