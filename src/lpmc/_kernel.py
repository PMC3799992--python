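"""Compiled Metropolis inner loop for the bond-fluctuation chain.

The kernel mirrors the reference sums in :mod:`lpmc.energetics` but keeps
three lattice-sized work grids so each trial move costs O(shell) instead of
O(N):

* ``occ``    - uint8, cube-covered sites (solvent emptiness test),
* ``agrid``  - int64, wrapped anchor site -> node index + 1,
* ``phi``    - float64, the solvent field Phi(s) = sum over nodes m within
  r_c of U(f_s * eps_m, r^2).  When a cube footprint covers/uncovers a site
  the solvent terms other nodes lose/regain are read off Phi in O(1).

The running total energy is advanced incrementally from the accepted dE and
periodically audited against a full recomputation; bond and excluded-volume
invariants are re-validated at the same cadence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .energetics import _enumerate_shell

SHELL, SHELL_R2, SHELL_OWN = _enumerate_shell()
SHELL = np.ascontiguousarray(SHELL)
SHELL_R2 = np.ascontiguousarray(SHELL_R2)
SHELL_OWN = np.ascontiguousarray(SHELL_OWN.astype(np.uint8))

BOND_OK = np.zeros(12, dtype=np.uint8)
for _b in (4, 5, 6, 9, 10):
    BOND_OK[_b] = 1

# cube vertex offsets
CUBE = np.array(
    [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
)


@njit(cache=True, inline="always")
def _wrap(v, L):
    if v >= L:
        return v - L
    if v < 0:
        return v + L
    return v


@njit(cache=True)
def _build_grids(posw, L, use_solvent, types, stab, shell, shell_r2):
    occ = np.zeros((L, L, L), dtype=np.uint8)
    agrid = np.zeros((L, L, L), dtype=np.int64)
    phi = np.zeros((1, 1, 1), dtype=np.float64)
    if use_solvent:
        phi = np.zeros((L, L, L), dtype=np.float64)
    n = posw.shape[0]
    for i in range(n):
        x, y, z = posw[i, 0], posw[i, 1], posw[i, 2]
        agrid[x, y, z] = i + 1
        for c in range(8):
            occ[
                _wrap(x + CUBE[c, 0], L), _wrap(y + CUBE[c, 1], L), _wrap(z + CUBE[c, 2], L)
            ] += 1
        if use_solvent:
            t = types[i]
            for k in range(shell.shape[0]):
                phi[
                    _wrap(x + shell[k, 0], L),
                    _wrap(y + shell[k, 1], L),
                    _wrap(z + shell[k, 2], L),
                ] += stab[t, shell_r2[k]]
    return occ, agrid, phi


@njit(cache=True)
def _local_energy(
    ix, iy, iz, i, ti, types, occ, agrid, utab, stab, use_solvent,
    shell, shell_r2, shell_own, L,
):
    """Pair + solvent energy of node i if its anchor sat at (ix, iy, iz).

    The node's own cube and anchor must already be absent from the grids.
    """
    e = 0.0
    for k in range(shell.shape[0]):
        sx = _wrap(ix + shell[k, 0], L)
        sy = _wrap(iy + shell[k, 1], L)
        sz = _wrap(iz + shell[k, 2], L)
        r2 = shell_r2[k]
        a = agrid[sx, sy, sz]
        if a > 0:
            m = a - 1
            if m != i - 1 and m != i + 1:
                e += utab[ti, types[m], r2]
        if use_solvent and shell_own[k] == 0 and occ[sx, sy, sz] == 0:
            e += stab[ti, r2]
    return e


@njit(cache=True)
def _full_energy(
    posw, types, occ, agrid, utab, stab, use_solvent, shell, shell_r2, shell_own, L
):
    """Total energy by explicit recomputation (pairs counted once)."""
    n = posw.shape[0]
    e_pair2 = 0.0
    e_solv = 0.0
    for i in range(n):
        ti = types[i]
        ix, iy, iz = posw[i, 0], posw[i, 1], posw[i, 2]
        for k in range(shell.shape[0]):
            sx = _wrap(ix + shell[k, 0], L)
            sy = _wrap(iy + shell[k, 1], L)
            sz = _wrap(iz + shell[k, 2], L)
            r2 = shell_r2[k]
            a = agrid[sx, sy, sz]
            if a > 0:
                m = a - 1
                if m != i and m != i - 1 and m != i + 1:
                    e_pair2 += utab[ti, types[m], r2]
            if use_solvent and shell_own[k] == 0 and occ[sx, sy, sz] == 0:
                e_solv += stab[ti, r2]
    return 0.5 * e_pair2 + e_solv


@njit(cache=True)
def _node_energies(
    posw, types, occ, agrid, utab, stab, use_solvent, shell, shell_r2, shell_own, L
):
    n = posw.shape[0]
    out = np.zeros(n)
    for i in range(n):
        ti = types[i]
        ix, iy, iz = posw[i, 0], posw[i, 1], posw[i, 2]
        for k in range(shell.shape[0]):
            sx = _wrap(ix + shell[k, 0], L)
            sy = _wrap(iy + shell[k, 1], L)
            sz = _wrap(iz + shell[k, 2], L)
            r2 = shell_r2[k]
            a = agrid[sx, sy, sz]
            if a > 0:
                m = a - 1
                if m != i and m != i - 1 and m != i + 1:
                    out[i] += utab[ti, types[m], r2]
            if use_solvent and shell_own[k] == 0 and occ[sx, sy, sz] == 0:
                out[i] += stab[ti, r2]
    return out


@njit(cache=True)
def _audit_geometry(pos, posw, occ, L):
    """Count bond-window and excluded-volume violations (0 = healthy)."""
    n = pos.shape[0]
    bad = 0
    for i in range(1, n):
        b2 = 0
        for d in range(3):
            dd = pos[i, d] - pos[i - 1, d]
            b2 += dd * dd
        if b2 > 11 or BOND_OK[b2] == 0:
            bad += 1
    # occupancy grid must be exactly the union of disjoint cubes: 8N covered sites
    covered = 0
    for x in range(L):
        for y in range(L):
            for z in range(L):
                if occ[x, y, z] > 1:
                    bad += 1
                covered += occ[x, y, z]
    if covered != 8 * n:
        bad += 1
    for i in range(n):
        for d in range(3):
            if (pos[i, d] - posw[i, d]) % L != 0:
                bad += 1
    return bad


@njit(cache=True)
def run_chain(
    pos,            # (N, 3) int64 unwrapped anchor coordinates; modified in place
    types,          # (N,) int64 node type indices
    L,              # box edge
    n_sweeps,       # number of MCS to run
    T,              # reduced temperature
    utab,           # (20, 20, 9) pair energy lookup
    stab,           # (20, 9) solvent energy lookup
    use_solvent,    # bool: any non-zero solvent couplings
    dump_interval,  # record observables every this many MCS
    audit_interval, # full-recompute audit cadence in MCS
    seed,           # RNG seed for the move stream
):
    """Run ``n_sweeps`` MCS of single-node Metropolis dynamics.

    Returns (frames, energies, attempts, accepts, max_drift, violations) with
    one record at t=0 and one per dump interval; attempts/accepts are
    per-node cumulative counters at each dump.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    shell, shell_r2, shell_own = SHELL, SHELL_R2, SHELL_OWN
    posw = np.empty_like(pos)
    for i in range(n):
        for d in range(3):
            posw[i, d] = pos[i, d] % L
    occ, agrid, phi = _build_grids(posw, L, use_solvent, types, stab, shell, shell_r2)

    n_dumps = n_sweeps // dump_interval
    frames = np.zeros((n_dumps + 1, n, 3), dtype=np.int64)
    energies = np.zeros(n_dumps + 1)
    attempts = np.zeros((n_dumps + 1, n), dtype=np.int64)
    accepts = np.zeros((n_dumps + 1, n), dtype=np.int64)
    att = np.zeros(n, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)

    e_run = _full_energy(
        posw, types, occ, agrid, utab, stab, use_solvent, shell, shell_r2, shell_own, L
    )
    frames[0] = pos
    energies[0] = e_run
    max_drift = 0.0
    violations = 0
    rec = 0

    for sweep in range(1, n_sweeps + 1):
        for _ in range(n):
            i = np.random.randint(0, n)
            axis = np.random.randint(0, 6)
            step = 1 if axis % 2 == 0 else -1
            axis //= 2
            att[i] += 1

            ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
            cx, cy, cz = ox, oy, oz
            if axis == 0:
                cx += step
            elif axis == 1:
                cy += step
            else:
                cz += step

            # bond window with chain neighbours
            if i > 0:
                b2 = (
                    (cx - pos[i - 1, 0]) ** 2
                    + (cy - pos[i - 1, 1]) ** 2
                    + (cz - pos[i - 1, 2]) ** 2
                )
                if b2 > 11 or BOND_OK[b2] == 0:
                    continue
            if i < n - 1:
                b2 = (
                    (cx - pos[i + 1, 0]) ** 2
                    + (cy - pos[i + 1, 1]) ** 2
                    + (cz - pos[i + 1, 2]) ** 2
                )
                if b2 > 11 or BOND_OK[b2] == 0:
                    continue

            wx, wy, wz = posw[i, 0], posw[i, 1], posw[i, 2]
            # wrapped candidate anchor
            nwx, nwy, nwz = wx, wy, wz
            if axis == 0:
                nwx = _wrap(wx + step, L)
            elif axis == 1:
                nwy = _wrap(wy + step, L)
            else:
                nwz = _wrap(wz + step, L)

            # excluded volume: the 4 newly covered sites must be free.
            # Moving +1 along an axis covers plane old+2; moving -1 covers old-1.
            if step == 1:
                lead = 2
            else:
                lead = -1
            blocked = False
            if axis == 0:
                px = _wrap(wx + lead, L)
                for b in range(2):
                    for c in range(2):
                        if occ[px, _wrap(wy + b, L), _wrap(wz + c, L)]:
                            blocked = True
            elif axis == 1:
                py = _wrap(wy + lead, L)
                for b in range(2):
                    for c in range(2):
                        if occ[_wrap(wx + b, L), py, _wrap(wz + c, L)]:
                            blocked = True
            else:
                pz = _wrap(wz + lead, L)
                for b in range(2):
                    for c in range(2):
                        if occ[_wrap(wx + b, L), _wrap(wy + c, L), pz]:
                            blocked = True
            if blocked:
                continue

            ti = types[i]
            # lift the node off the grids
            agrid[wx, wy, wz] = 0
            for c in range(8):
                occ[
                    _wrap(wx + CUBE[c, 0], L),
                    _wrap(wy + CUBE[c, 1], L),
                    _wrap(wz + CUBE[c, 2], L),
                ] = 0

            e_old = _local_energy(
                wx, wy, wz, i, ti, types, occ, agrid, utab, stab, use_solvent,
                shell, shell_r2, shell_own, L,
            )
            e_new = _local_energy(
                nwx, nwy, nwz, i, ti, types, occ, agrid, utab, stab, use_solvent,
                shell, shell_r2, shell_own, L,
            )
            de = e_new - e_old

            if use_solvent:
                # solvent terms other nodes regain at freed sites / lose at
                # newly covered sites, read from phi minus the node's own field
                d_block = 0.0
                for b in range(2):
                    for c in range(2):
                        # freed: trailing face of the old cube
                        if step == 1:
                            trail = 0
                        else:
                            trail = 1
                        if axis == 0:
                            fx, fy, fz = wx, _wrap(wy + b, L), _wrap(wz + c, L)
                            fx = _wrap(wx + trail, L)
                            gx = _wrap(wx + lead, L)
                            gy, gz = fy, fz
                            d2f = trail * trail + b * b + c * c
                            d2g = lead * lead + b * b + c * c
                        elif axis == 1:
                            fy = _wrap(wy + trail, L)
                            fx, fz = _wrap(wx + b, L), _wrap(wz + c, L)
                            gy = _wrap(wy + lead, L)
                            gx, gz = fx, fz
                            d2f = trail * trail + b * b + c * c
                            d2g = lead * lead + b * b + c * c
                        else:
                            fz = _wrap(wz + trail, L)
                            fx, fy = _wrap(wx + b, L), _wrap(wy + c, L)
                            gz = _wrap(wz + lead, L)
                            gx, gy = fx, fy
                            d2f = trail * trail + b * b + c * c
                            d2g = lead * lead + b * b + c * c
                        own_f = stab[ti, d2f] if d2f > 0 else 0.0
                        own_g = stab[ti, d2g]
                        d_block += phi[fx, fy, fz] - own_f
                        d_block -= phi[gx, gy, gz] - own_g
                de += d_block

            if de <= 0.0 or np.random.random() < np.exp(-de / T):
                # accept: place at candidate
                pos[i, 0], pos[i, 1], pos[i, 2] = cx, cy, cz
                posw[i, 0], posw[i, 1], posw[i, 2] = nwx, nwy, nwz
                agrid[nwx, nwy, nwz] = i + 1
                for c in range(8):
                    occ[
                        _wrap(nwx + CUBE[c, 0], L),
                        _wrap(nwy + CUBE[c, 1], L),
                        _wrap(nwz + CUBE[c, 2], L),
                    ] = 1
                if use_solvent:
                    for k in range(shell.shape[0]):
                        v = stab[ti, shell_r2[k]]
                        phi[
                            _wrap(wx + shell[k, 0], L),
                            _wrap(wy + shell[k, 1], L),
                            _wrap(wz + shell[k, 2], L),
                        ] -= v
                        phi[
                            _wrap(nwx + shell[k, 0], L),
                            _wrap(nwy + shell[k, 1], L),
                            _wrap(nwz + shell[k, 2], L),
                        ] += v
                e_run += de
                acc[i] += 1
            else:
                # reject: restore grids
                agrid[wx, wy, wz] = i + 1
                for c in range(8):
                    occ[
                        _wrap(wx + CUBE[c, 0], L),
                        _wrap(wy + CUBE[c, 1], L),
                        _wrap(wz + CUBE[c, 2], L),
                    ] = 1

        if sweep % dump_interval == 0:
            rec += 1
            frames[rec] = pos
            energies[rec] = e_run
            attempts[rec] = att
            accepts[rec] = acc
        if audit_interval > 0 and sweep % audit_interval == 0:
            e_f = _full_energy(
                posw, types, occ, agrid, utab, stab, use_solvent,
                shell, shell_r2, shell_own, L,
            )
            drift = abs(e_run - e_f)
            if drift > max_drift:
                max_drift = drift
            e_run = e_f
            violations += _audit_geometry(pos, posw, occ, L)

    return frames, energies, attempts, accepts, max_drift, violations
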