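"""Numba hot loop for the athermal hard-core Monte Carlo engine.

The acceptance rule for an athermal hard-sphere system is reject-on-violation:
a proposed move is accepted iff no excluded pair overlaps, no sphere crosses
the wall, and all bond lengths are preserved (rotational and rigid moves
preserve them by construction).  All proposal distributions are symmetric.

Move classes (tally index):
  0  single-sphere displacement (free particles; rigid 1-chains)
  1  crankshaft rotation about the two bonded neighbors
  2  pivot: terminal/tail/branch rotation about one hinge bead
  3  ring-segment crankshaft carrying attached branches rigidly
  4  rigid whole-chain translation
"""

import numba
import numpy as np
from numba import njit

F8 = numba.float64
I4 = numba.int32
I8 = numba.int64


@njit(cache=True, inline="always")
def _inside_wall(x, y, z, margin, R, half_axis):
    ax = min(max(x, -half_axis), half_axis)
    dx = x - ax
    d2 = dx * dx + y * y + z * z
    rr = R - margin
    return d2 <= rr * rr + 1e-7


@njit(cache=True, inline="always")
def _cell_index(x, y, z, ox, oy, oz, cs, nx, ny, nz):
    ix = int((x - ox) / cs)
    iy = int((y - oy) / cs)
    iz = int((z - oz) / cs)
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz >= nz:
        iz = nz - 1
    return (ix * ny + iy) * nz + iz


@njit(cache=True)
def build_cell_list(pos, ox, oy, oz, cs, nx, ny, nz, head, nxt, cellof):
    head[:] = -1
    for i in range(pos.shape[0]):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], ox, oy, oz, cs, nx, ny, nz)
        cellof[i] = c
        nxt[i] = head[c]
        head[c] = i


@njit(cache=True, inline="always")
def _cell_remove(i, head, nxt, cellof):
    c = cellof[i]
    j = head[c]
    if j == i:
        head[c] = nxt[i]
        return
    while nxt[j] != i:
        j = nxt[j]
    nxt[j] = nxt[i]


@njit(cache=True, inline="always")
def _cell_insert(i, c, head, nxt, cellof):
    cellof[i] = c
    nxt[i] = head[c]
    head[c] = i


@njit(cache=True, inline="always")
def _is_bonded(i, q, adj):
    for t in range(adj.shape[1]):
        a = adj[i, t]
        if a == -1:
            return False
        if a == q:
            return True
    return False


@njit(cache=True)
def _sphere_ok(idx, px, py, pz, r, scode, pos, rad, sp, excl, adj, stamp, cur,
               head, nxt, ox, oy, oz, cs, nx, ny, nz, R, half_axis):
    if not _inside_wall(px, py, pz, r, R, half_axis):
        return False
    ix = int((px - ox) / cs)
    iy = int((py - oy) / cs)
    iz = int((pz - oz) / cs)
    for a in range(max(ix - 1, 0), min(ix + 2, nx)):
        for b in range(max(iy - 1, 0), min(iy + 2, ny)):
            for c in range(max(iz - 1, 0), min(iz + 2, nz)):
                q = head[(a * ny + b) * nz + c]
                while q != -1:
                    if q != idx and stamp[q] != cur and excl[scode, sp[q]]:
                        if not _is_bonded(idx, q, adj):
                            dx = px - pos[q, 0]
                            dy = py - pos[q, 1]
                            dz = pz - pos[q, 2]
                            s = r + rad[q]
                            if dx * dx + dy * dy + dz * dz < s * s * (1.0 - 1e-12):
                                return False
                    q = nxt[q]
    return True


@njit(cache=True)
def _try_commit(k, mv, newp, pos, rad, sp, excl, adj, twin, has_rider,
                stamp, cur, head, nxt, cellof,
                ox, oy, oz, cs, nx, ny, nz, R, half_axis):
    """Check the k moved beads (+ riders) at their proposed positions; commit
    positions and cell-list membership if clean.  Returns acceptance."""
    # mark moved set so intra-set pairs (rigidly preserved) are skipped
    for m in range(k):
        i = mv[m]
        stamp[i] = cur
        if has_rider[i]:
            stamp[twin[i]] = cur
    ok = True
    for m in range(k):
        i = mv[m]
        px = newp[m, 0]
        py = newp[m, 1]
        pz = newp[m, 2]
        if not _sphere_ok(i, px, py, pz, rad[i], sp[i], pos, rad, sp, excl, adj,
                          stamp, cur, head, nxt, ox, oy, oz, cs, nx, ny, nz,
                          R, half_axis):
            ok = False
            break
        if has_rider[i]:
            j = twin[i]
            if not _sphere_ok(j, px, py, pz, rad[j], sp[j], pos, rad, sp, excl,
                              adj, stamp, cur, head, nxt, ox, oy, oz, cs,
                              nx, ny, nz, R, half_axis):
                ok = False
                break
    if ok:
        for m in range(k):
            i = mv[m]
            pos[i, 0] = newp[m, 0]
            pos[i, 1] = newp[m, 1]
            pos[i, 2] = newp[m, 2]
            c = _cell_index(newp[m, 0], newp[m, 1], newp[m, 2],
                            ox, oy, oz, cs, nx, ny, nz)
            if c != cellof[i]:
                _cell_remove(i, head, nxt, cellof)
                _cell_insert(i, c, head, nxt, cellof)
            if has_rider[i]:
                j = twin[i]
                pos[j, 0] = newp[m, 0]
                pos[j, 1] = newp[m, 1]
                pos[j, 2] = newp[m, 2]
                if c != cellof[j]:
                    _cell_remove(j, head, nxt, cellof)
                    _cell_insert(j, c, head, nxt, cellof)
    return ok


@njit(cache=True, inline="always")
def _random_unit():
    while True:
        ux = np.random.normal()
        uy = np.random.normal()
        uz = np.random.normal()
        n2 = ux * ux + uy * uy + uz * uz
        if n2 > 1e-12:
            n = np.sqrt(n2)
            return ux / n, uy / n, uz / n


@njit(cache=True, inline="always")
def _rotate_into(m, mv, newp, pos, ax, ay, az, ux, uy, uz, ct, st):
    """newp[m] = rotation of pos[mv[m]] about axis (a, u) by angle (ct, st)."""
    i = mv[m]
    vx = pos[i, 0] - ax
    vy = pos[i, 1] - ay
    vz = pos[i, 2] - az
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    omc = 1.0 - ct
    newp[m, 0] = ax + vx * ct + cx * st + ux * dot * omc
    newp[m, 1] = ay + vy * ct + cy * st + uy * dot * omc
    newp[m, 2] = az + vz * ct + cz * st + uz * dot * omc


@njit(cache=True)
def run_sweeps(
    # particle state
    pos, rad, sp, excl, adj, twin, has_rider, stamp,
    # movers and topology
    movers, kind,
    ch_id, ch_off, ch_indptr, ch_beads,
    br_id, br_off, br_indptr, br_beads, br_anchor,
    rpos, ring_order, ratt_indptr, ratt_beads,
    # cell list
    head, nxt, cellof, ox, oy, oz, cs, nx, ny, nz,
    # geometry
    R, half_axis,
    # schedule
    amp, seg_max, n_sweeps, seed,
    # scratch + tallies
    mv, newp, att, acc, stamp_start,
):
    """Run ``n_sweeps`` sweeps (one attempted move per mover on average)."""
    np.random.seed(seed)
    cur = stamp_start
    M = movers.shape[0]
    n_ring = ring_order.shape[0]
    for _ in range(n_sweeps):
        for _ in range(M):
            cur += 1
            mi = movers[np.random.randint(M)]
            kd = kind[mi]
            k = 0
            cls = 0
            if kd == 0:
                cls = 0
                d = amp[0]
                mv[0] = mi
                newp[0, 0] = pos[mi, 0] + np.random.uniform(-d, d)
                newp[0, 1] = pos[mi, 1] + np.random.uniform(-d, d)
                newp[0, 2] = pos[mi, 2] + np.random.uniform(-d, d)
                k = 1
            elif kd == 1:
                # polysome chain bead
                c0 = ch_id[mi]
                s = ch_indptr[c0]
                e = ch_indptr[c0 + 1]
                n = e - s
                o = ch_off[mi]
                u = np.random.random()
                if n == 1 or u >= 0.85:
                    cls = 4
                    d = amp[4]
                    tx = np.random.uniform(-d, d)
                    ty = np.random.uniform(-d, d)
                    tz = np.random.uniform(-d, d)
                    for t in range(n):
                        b = ch_beads[s + t]
                        mv[t] = b
                        newp[t, 0] = pos[b, 0] + tx
                        newp[t, 1] = pos[b, 1] + ty
                        newp[t, 2] = pos[b, 2] + tz
                    k = n
                elif u < 0.55 and o > 0 and o < n - 1:
                    cls = 1
                    a = ch_beads[s + o - 1]
                    b = ch_beads[s + o + 1]
                    axx = pos[a, 0]
                    axy = pos[a, 1]
                    axz = pos[a, 2]
                    ux = pos[b, 0] - axx
                    uy = pos[b, 1] - axy
                    uz = pos[b, 2] - axz
                    n2 = ux * ux + uy * uy + uz * uz
                    if n2 < 1e-12:
                        ux, uy, uz = _random_unit()
                    else:
                        nn = np.sqrt(n2)
                        ux /= nn
                        uy /= nn
                        uz /= nn
                    th = np.random.uniform(-amp[1], amp[1])
                    mv[0] = mi
                    _rotate_into(0, mv, newp, pos, axx, axy, axz,
                                 ux, uy, uz, np.cos(th), np.sin(th))
                    k = 1
                else:
                    # pivot of the shorter chain side about its hinge
                    cls = 2
                    if o <= n - 1 - o:
                        hinge = ch_beads[s + o + 1] if o < n - 1 else ch_beads[s + o - 1]
                        lo = 0
                        hi = o
                    else:
                        hinge = ch_beads[s + o - 1]
                        lo = o
                        hi = n - 1
                    ux, uy, uz = _random_unit()
                    th = np.random.uniform(-amp[2], amp[2])
                    ct = np.cos(th)
                    st = np.sin(th)
                    k = 0
                    for t in range(lo, hi + 1):
                        mv[k] = ch_beads[s + t]
                        k += 1
                    for t in range(k):
                        _rotate_into(t, mv, newp, pos,
                                     pos[hinge, 0], pos[hinge, 1], pos[hinge, 2],
                                     ux, uy, uz, ct, st)
            elif kd == 2:
                # DNA branch bead
                b0 = br_id[mi]
                s = br_indptr[b0]
                e = br_indptr[b0 + 1]
                n = e - s
                o = br_off[mi]
                parent = br_anchor[b0] if o == 0 else br_beads[s + o - 1]
                u = np.random.random()
                if u < 0.5 and o < n - 1:
                    cls = 1
                    child = br_beads[s + o + 1]
                    axx = pos[parent, 0]
                    axy = pos[parent, 1]
                    axz = pos[parent, 2]
                    ux = pos[child, 0] - axx
                    uy = pos[child, 1] - axy
                    uz = pos[child, 2] - axz
                    n2 = ux * ux + uy * uy + uz * uz
                    if n2 < 1e-12:
                        ux, uy, uz = _random_unit()
                    else:
                        nn = np.sqrt(n2)
                        ux /= nn
                        uy /= nn
                        uz /= nn
                    th = np.random.uniform(-amp[1], amp[1])
                    mv[0] = mi
                    _rotate_into(0, mv, newp, pos, axx, axy, axz,
                                 ux, uy, uz, np.cos(th), np.sin(th))
                    k = 1
                else:
                    # downstream pivot about the parent bead
                    cls = 2
                    ux, uy, uz = _random_unit()
                    th = np.random.uniform(-amp[2], amp[2])
                    ct = np.cos(th)
                    st = np.sin(th)
                    k = 0
                    for t in range(o, n):
                        mv[k] = br_beads[s + t]
                        k += 1
                    for t in range(k):
                        _rotate_into(t, mv, newp, pos,
                                     pos[parent, 0], pos[parent, 1], pos[parent, 2],
                                     ux, uy, uz, ct, st)
            else:
                # ring bead: segment crankshaft carrying attached branches
                cls = 3
                if n_ring < 4:
                    continue
                seg = 1 + np.random.randint(min(seg_max, n_ring - 2))
                p0 = rpos[mi]
                a = ring_order[(p0 - 1) % n_ring]
                b = ring_order[(p0 + seg) % n_ring]
                axx = pos[a, 0]
                axy = pos[a, 1]
                axz = pos[a, 2]
                ux = pos[b, 0] - axx
                uy = pos[b, 1] - axy
                uz = pos[b, 2] - axz
                n2 = ux * ux + uy * uy + uz * uz
                if n2 < 1e-12:
                    ux, uy, uz = _random_unit()
                else:
                    nn = np.sqrt(n2)
                    ux /= nn
                    uy /= nn
                    uz /= nn
                th = np.random.uniform(-amp[3], amp[3])
                ct = np.cos(th)
                st = np.sin(th)
                k = 0
                for t in range(seg):
                    rp = (p0 + t) % n_ring
                    rb = ring_order[rp]
                    mv[k] = rb
                    k += 1
                    for w in range(ratt_indptr[rp], ratt_indptr[rp + 1]):
                        mv[k] = ratt_beads[w]
                        k += 1
                for t in range(k):
                    _rotate_into(t, mv, newp, pos, axx, axy, axz,
                                 ux, uy, uz, ct, st)
            att[cls] += 1
            if k > 0 and _try_commit(
                k, mv, newp, pos, rad, sp, excl, adj, twin, has_rider,
                stamp, cur, head, nxt, cellof,
                ox, oy, oz, cs, nx, ny, nz, R, half_axis,
            ):
                acc[cls] += 1
    return cur
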