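"""Numba-compiled inner loops of the DPD engine.

Everything here works on plain float64/int64 arrays in reduced units
(r_c = m = k_BT = 1).  Neighbor search sorts beads by cell each step
(counting sort) so the pair loops run over contiguous memory, with a
precomputed half-space neighbor-cell table.

The per-pair random force is generated from a counter-based splitmix64
hash of (step, ordered pair, seed), so a trajectory is bit-reproducible
regardless of how pairs are enumerated.  Pair noise is a uniform variate
on [-sqrt(3), sqrt(3)] (zero mean, unit variance), which is sufficient
for the DPD thermostat.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT3 = np.sqrt(3.0)

# status codes returned by run_steps
OK = 0
UNSTABLE = 1  # single-step displacement exceeded L/2
NAN = 2

_U64 = np.uint64


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + _U64(0x9E3779B97F4A7C15)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _pair_uniform(step, i, j, seed):
    """Symmetric per-(step, pair) uniform variate on [-sqrt3, sqrt3)."""
    if i > j:
        i, j = j, i
    h = _splitmix64(_U64(seed))
    h = _splitmix64(h ^ _U64(step))
    h = _splitmix64(h ^ (_U64(i) << _U64(21)) ^ _U64(j))
    u = np.float64(h >> _U64(11)) / 9007199254740992.0  # [0, 1)
    return _SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, inline="always", fastmath=True)
def _fold(d, L, half):
    # wrapped coordinates guarantee |d| < L, so one fold suffices
    if d > half:
        return d - L
    if d < -half:
        return d + L
    return d


def build_neighbor_table(ncell: int) -> np.ndarray:
    """Half-space neighbor cell indices, (ncell^3, 13)."""
    offsets = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ]
    table = np.empty((ncell**3, 13), dtype=np.int64)
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                for k, (ox, oy, oz) in enumerate(offsets):
                    table[c, k] = (
                        ((cx + ox) % ncell * ncell + (cy + oy) % ncell) * ncell
                        + (cz + oz) % ncell
                    )
    return table


@njit(cache=True, fastmath=True)
def _sort_by_cell(pos, L, ncell, order, start):
    """Counting sort of bead indices by cell; fills `order` and `start`."""
    n = pos.shape[0]
    ncells = ncell * ncell * ncell
    inv = ncell / L
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = np.int64(pos[i, 0] * inv) % ncell
        iy = np.int64(pos[i, 1] * inv) % ncell
        iz = np.int64(pos[i, 2] * inv) % ncell
        cell_of[i] = (ix * ncell + iy) * ncell + iz
    start[:] = 0
    for i in range(n):
        start[cell_of[i] + 1] += 1
    for c in range(ncells):
        start[c + 1] += start[c]
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1


@njit(cache=True, fastmath=True)
def compute_forces(
    pos, vel, sidx, A, bonds, bond_k, L,
    gamma, sigma, dt, step, seed,
    forces, ncell, nbr, order, start,
):
    """Total conservative + dissipative + random + bond force, in place."""
    n = pos.shape[0]
    half = 0.5 * L
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    forces[:] = 0.0
    if ncell >= 3:
        _sort_by_cell(pos, L, ncell, order, start)
        # gather into cell-sorted scratch for contiguous access
        spos = np.empty((n, 3))
        svel = np.empty((n, 3))
        sfrc = np.zeros((n, 3))
        ssp = np.empty(n, dtype=np.int64)
        for k in range(n):
            i = order[k]
            spos[k, 0] = pos[i, 0]
            spos[k, 1] = pos[i, 1]
            spos[k, 2] = pos[i, 2]
            svel[k, 0] = vel[i, 0]
            svel[k, 1] = vel[i, 1]
            svel[k, 2] = vel[i, 2]
            ssp[k] = sidx[i]
        ncells = ncell * ncell * ncell
        # kk = 13 stands for the remainder of the bead's own cell
        for c in range(ncells):
            lo, hi = start[c], start[c + 1]
            for a_ in range(lo, hi):
                for kk in range(14):
                    if kk == 13:
                        lo2, hi2 = a_ + 1, hi
                    else:
                        c2 = nbr[c, kk]
                        lo2, hi2 = start[c2], start[c2 + 1]
                    for b_ in range(lo2, hi2):
                        dx = _fold(spos[a_, 0] - spos[b_, 0], L, half)
                        dy = _fold(spos[a_, 1] - spos[b_, 1], L, half)
                        dz = _fold(spos[a_, 2] - spos[b_, 2], L, half)
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 >= 1.0:
                            continue
                        a_ij = A[ssp[a_], ssp[b_]]
                        if r2 > 1e-24:
                            r = np.sqrt(r2)
                            w = 1.0 - r
                            ex, ey, ez = dx / r, dy / r, dz / r
                            rv = (
                                ex * (svel[a_, 0] - svel[b_, 0])
                                + ey * (svel[a_, 1] - svel[b_, 1])
                                + ez * (svel[a_, 2] - svel[b_, 2])
                            )
                            theta = _pair_uniform(step, order[a_], order[b_], seed)
                            f = (
                                a_ij * w
                                - gamma * w * w * rv
                                + sigma * w * theta * inv_sqrt_dt
                            )
                        else:
                            # coincident beads: capped push along a hashed direction
                            t1 = _pair_uniform(step, order[a_], order[b_], seed)
                            t2 = _pair_uniform(step + 1, order[a_], order[b_], seed)
                            ex = np.cos(2.0 * t1)
                            ey = np.sin(2.0 * t1) * np.cos(2.0 * t2)
                            ez = np.sin(2.0 * t1) * np.sin(2.0 * t2)
                            f = a_ij
                        sfrc[a_, 0] += f * ex
                        sfrc[a_, 1] += f * ey
                        sfrc[a_, 2] += f * ez
                        sfrc[b_, 0] -= f * ex
                        sfrc[b_, 1] -= f * ey
                        sfrc[b_, 2] -= f * ez
        for k in range(n):
            i = order[k]
            forces[i, 0] = sfrc[k, 0]
            forces[i, 1] = sfrc[k, 1]
            forces[i, 2] = sfrc[k, 2]
    else:  # box too small for a cell grid: all pairs
        for i in range(n):
            for j in range(i + 1, n):
                _pair_direct(
                    i, j, pos, vel, sidx, A, L, half, gamma, sigma,
                    inv_sqrt_dt, step, seed, forces,
                )
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = _fold(pos[i, 0] - pos[j, 0], L, half)
        dy = _fold(pos[i, 1] - pos[j, 1], L, half)
        dz = _fold(pos[i, 2] - pos[j, 2], L, half)
        forces[i, 0] -= bond_k * dx
        forces[i, 1] -= bond_k * dy
        forces[i, 2] -= bond_k * dz
        forces[j, 0] += bond_k * dx
        forces[j, 1] += bond_k * dy
        forces[j, 2] += bond_k * dz


@njit(cache=True, inline="always", fastmath=True)
def _pair_direct(i, j, pos, vel, sidx, A, L, half, gamma, sigma, inv_sqrt_dt, step, seed, forces):
    dx = _fold(pos[i, 0] - pos[j, 0], L, half)
    dy = _fold(pos[i, 1] - pos[j, 1], L, half)
    dz = _fold(pos[i, 2] - pos[j, 2], L, half)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= 1.0:
        return
    a_ij = A[sidx[i], sidx[j]]
    if r2 > 1e-24:
        r = np.sqrt(r2)
        w = 1.0 - r
        ex, ey, ez = dx / r, dy / r, dz / r
        rv = (
            ex * (vel[i, 0] - vel[j, 0])
            + ey * (vel[i, 1] - vel[j, 1])
            + ez * (vel[i, 2] - vel[j, 2])
        )
        theta = _pair_uniform(step, i, j, seed)
        f = a_ij * w - gamma * w * w * rv + sigma * w * theta * inv_sqrt_dt
    else:
        t1 = _pair_uniform(step, i, j, seed)
        t2 = _pair_uniform(step + 1, i, j, seed)
        ex = np.cos(2.0 * t1)
        ey = np.sin(2.0 * t1) * np.cos(2.0 * t2)
        ez = np.sin(2.0 * t1) * np.sin(2.0 * t2)
        f = a_ij
    forces[i, 0] += f * ex
    forces[i, 1] += f * ey
    forces[i, 2] += f * ez
    forces[j, 0] -= f * ex
    forces[j, 1] -= f * ey
    forces[j, 2] -= f * ez


@njit(cache=True, fastmath=True)
def run_steps(
    pos, unwrap, vel, forces, sidx, A, bonds, bond_k, L,
    gamma, sigma, dt, lam, seed, step0, n_steps,
    ncell, nbr, order, start, vtilde, new_forces,
):
    """Advance n_steps with the modified velocity-Verlet scheme.

    pos/unwrap/vel/forces are updated in place; forces must hold the
    force at step0 on entry.  Returns a status code.
    """
    half = 0.5 * L
    for s in range(step0, step0 + n_steps):
        for i in range(pos.shape[0]):
            for d in range(3):
                dxi = dt * vel[i, d] + 0.5 * dt * dt * forces[i, d]
                if np.abs(dxi) > half:
                    return UNSTABLE
                p = pos[i, d] + dxi
                pos[i, d] = p - L * np.floor(p / L)
                unwrap[i, d] += dxi
                vtilde[i, d] = vel[i, d] + lam * dt * forces[i, d]
        compute_forces(
            pos, vtilde, sidx, A, bonds, bond_k, L, gamma, sigma, dt,
            s + 1, seed, new_forces, ncell, nbr, order, start,
        )
        for i in range(pos.shape[0]):
            for d in range(3):
                vel[i, d] += 0.5 * dt * (forces[i, d] + new_forces[i, d])
                forces[i, d] = new_forces[i, d]
        if not np.isfinite(pos[0, 0]):
            return NAN
    return OK


@njit(cache=True, fastmath=True)
def cell_list_pairs(pos, L, ncell, nbr):
    """All periodic minimum-image pairs with r < 1 via the cell grid."""
    n = pos.shape[0]
    half = 0.5 * L
    order = np.empty(n, dtype=np.int64)
    start = np.zeros(ncell**3 + 1, dtype=np.int64)
    _sort_by_cell(pos, L, ncell, order, start)
    out = []
    for c in range(ncell**3):
        lo, hi = start[c], start[c + 1]
        for a_ in range(lo, hi):
            i = order[a_]
            for b_ in range(a_ + 1, hi):
                j = order[b_]
                if _dist2(pos, i, j, L, half) < 1.0:
                    out.append((min(i, j), max(i, j)))
            for kk in range(13):
                c2 = nbr[c, kk]
                for b_ in range(start[c2], start[c2 + 1]):
                    j = order[b_]
                    if _dist2(pos, i, j, L, half) < 1.0:
                        out.append((min(i, j), max(i, j)))
    return out


@njit(cache=True, inline="always", fastmath=True)
def _dist2(pos, i, j, L, half):
    dx = _fold(pos[i, 0] - pos[j, 0], L, half)
    dy = _fold(pos[i, 1] - pos[j, 1], L, half)
    dz = _fold(pos[i, 2] - pos[j, 2], L, half)
    return dx * dx + dy * dy + dz * dz
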