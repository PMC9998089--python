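"""Numba kernels for the Metropolis dynamics and ECM remodelling sweeps.

All per-voxel hot loops live here.  The packed parameter vector ``pp`` is
assembled by :mod:`invasim.engine`:

    pp[0]  lambda_volume
    pp[1]  lambda_surface
    pp[2]  temperature
    pp[3]  ecm entry barrier beta
    pp[4]  J(SCC, full-density matrix)
    pp[5]  J(SCC, zero-density matrix)
    pp[6]  CAF-CAF repulsion range (voxels)
    pp[7]  CAF-CAF repulsion penalty
    pp[8]  cue mode: 0 uniform, 1 radial
    pp[9:12]   uniform cue unit vector
    pp[12:15]  radial cue origin (voxel coordinates)
    pp[15] (reserved)
    pp[16] maximum matrix density a cell voxel may move into (steric limit)

``taxis_e`` holds the per-cell taxis energy with its type's coupling gain
already applied.

Cell bookkeeping arrays are indexed by cell id (slot 0 unused): ``kind``,
``vol`` (voxel count), ``surf`` (exposed face count), ``tvol``/``tsurf``
(targets), ``csum`` (coordinate sums, for centroids) and ``taxis_e`` (taxis
energy scale).  Lattice ids: 0 medium/matrix, -1 frozen air, >0 cells.
"""

import numpy as np
from numba import njit

K_MEDIUM = 0
K_SCC = 1
K_CAF = 2
K_AIR = 3

# 6-connectivity steps for face counting and the first six copy directions;
# the full 26-neighbourhood continues with edge and corner steps
_OFFS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFS += [(dx, dy, dz)
          for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
          if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) > 1]
_DX6 = np.array([o[0] for o in _OFFS], dtype=np.int64)
_DY6 = np.array([o[1] for o in _OFFS], dtype=np.int64)
_DZ6 = np.array([o[2] for o in _OFFS], dtype=np.int64)


@njit(cache=False)
def seed(value):
    """Seed numba's global RNG (used by metropolis_accept)."""
    np.random.seed(value)


_INV53 = 1.0 / (1 << 53)


@njit(inline="always")
def _xorshift(x):
    """xorshift64* step; returns (new_state, uniform double in [0, 1))."""
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    out = x * np.uint64(0x2545F4914F6CDD1D)
    return x, (out >> np.uint64(11)) * _INV53


def make_rng_state(seed_value: int) -> np.ndarray:
    """Non-zero uint64 xorshift state derived from an integer seed."""
    mixed = ((int(seed_value) * 0x9E3779B97F4A7C15 + 0x1234567) % (1 << 64)) | 1
    return np.array([mixed], dtype=np.uint64)


@njit(inline="always")
def _kind_of(cid, kind):
    if cid == 0:
        return K_MEDIUM
    if cid < 0:
        return K_AIR
    return kind[cid]


@njit(inline="always")
def _pair_energy(a, b, ka, kb, J, jfull, jzero, rho_a, rho_b):
    """Contact energy between voxel occupied by id ``a`` (density rho_a) and
    neighbour occupied by id ``b`` (density rho_b).  Same id -> no interface."""
    if a == b:
        return 0.0
    if ka == K_SCC and kb == K_MEDIUM:
        return jzero + (jfull - jzero) * rho_b
    if ka == K_MEDIUM and kb == K_SCC:
        return jzero + (jfull - jzero) * rho_a
    return J[ka, kb]


@njit(cache=False, fastmath=True)
def delta_h(grid, dens, kind, vol, surf, tvol, tsurf, csum, taxis_e, caf_ids,
            J, pp, sx, sy, sz, tx, ty, tz):
    """Energy change for copying the id at (sx,sy,sz) into (tx,ty,tz).

    Returns (dH, d_surface_source_cell, d_surface_target_cell).  The state is
    not modified.  A copy between voxels holding the same id costs nothing.
    """
    nx, ny, nz = grid.shape
    s_id = grid[sx, sy, sz]
    t_id = grid[tx, ty, tz]
    if s_id == t_id:
        return 0.0, 0, 0
    jfull = pp[4]
    jzero = pp[5]
    rho_t = dens[tx, ty, tz]
    ks = _kind_of(s_id, kind)
    kt = _kind_of(t_id, kind)

    dH = 0.0
    # contact term over the 26-neighbourhood of the changing voxel
    interior = (0 < tx < nx - 1) and (0 < ty < ny - 1) and (0 < tz < nz - 1)
    if interior:
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    if dx == 0 and dy == 0 and dz == 0:
                        continue
                    ax = tx + dx
                    ay = ty + dy
                    az = tz + dz
                    nid = grid[ax, ay, az]
                    kn = _kind_of(nid, kind)
                    rho_n = dens[ax, ay, az]
                    dH += _pair_energy(s_id, nid, ks, kn, J, jfull, jzero, rho_t, rho_n)
                    dH -= _pair_energy(t_id, nid, kt, kn, J, jfull, jzero, rho_t, rho_n)
    else:
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    if dx == 0 and dy == 0 and dz == 0:
                        continue
                    ax = tx + dx
                    ay = ty + dy
                    az = tz + dz
                    if ax < 0 or ax >= nx or ay < 0 or ay >= ny or az < 0 or az >= nz:
                        continue
                    nid = grid[ax, ay, az]
                    kn = _kind_of(nid, kind)
                    rho_n = dens[ax, ay, az]
                    dH += _pair_energy(s_id, nid, ks, kn, J, jfull, jzero, rho_t, rho_n)
                    dH -= _pair_energy(t_id, nid, kt, kn, J, jfull, jzero, rho_t, rho_n)

    # face-count (surface) changes for the gaining and losing cells
    ds_s = 0
    ds_t = 0
    for k in range(6):
        ax = tx + _DX6[k]
        ay = ty + _DY6[k]
        az = tz + _DZ6[k]
        if ax < 0 or ax >= nx or ay < 0 or ay >= ny or az < 0 or az >= nz:
            nid = -2147483648  # domain wall: matches no cell
        else:
            nid = grid[ax, ay, az]
        if s_id > 0:
            ds_s += -1 if nid == s_id else 1
        if t_id > 0:
            ds_t += 1 if nid == t_id else -1

    # volume and surface constraints
    lv = pp[0]
    ls = pp[1]
    if s_id > 0:
        v = float(vol[s_id])
        dH += lv * ((v + 1.0 - tvol[s_id]) ** 2 - (v - tvol[s_id]) ** 2)
        s0 = float(surf[s_id])
        dH += ls * ((s0 + ds_s - tsurf[s_id]) ** 2 - (s0 - tsurf[s_id]) ** 2)
    if t_id > 0:
        v = float(vol[t_id])
        dH += lv * ((v - 1.0 - tvol[t_id]) ** 2 - (v - tvol[t_id]) ** 2)
        s0 = float(surf[t_id])
        dH += ls * ((s0 + ds_t - tsurf[t_id]) ** 2 - (s0 - tsurf[t_id]) ** 2)

    # taxis: bias copies involving a motile cell along the local cue
    # direction; both extensions (cell gains the target voxel) and rear
    # retractions (medium reclaims a cell voxel) count, as in the usual
    # Potts chemotaxis convention
    if s_id > 0 or t_id > 0:
        e = taxis_e[s_id] if s_id > 0 else taxis_e[t_id]
        if e != 0.0:
            if pp[8] < 0.5:
                ux = pp[9]
                uy = pp[10]
                uz = pp[11]
            else:
                ux = tx - pp[12]
                uy = ty - pp[13]
                uz = tz - pp[14]
                nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                if nrm > 0.0:
                    ux /= nrm
                    uy /= nrm
                    uz /= nrm
            ddx = float(tx - sx)
            ddy = float(ty - sy)
            ddz = float(tz - sz)
            dn = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            dH += -e * (ux * ddx + uy * ddy + uz * ddz) / dn

    # matrix resists entry: a steric exclusion above the pore-opening
    # density threshold, plus a penalty proportional to residual density
    if t_id == 0 and s_id > 0:
        if rho_t > pp[16]:
            dH += 1e12  # pores too small: impassable until remodelled
        else:
            dH += pp[3] * rho_t

    # CAF-CAF repulsion on centroid approach within range
    if s_id > 0 and ks == K_CAF and caf_ids.shape[0] > 1:
        v = float(vol[s_id])
        cx = csum[s_id, 0] / v
        cy = csum[s_id, 1] / v
        cz = csum[s_id, 2] / v
        ncx = (csum[s_id, 0] + tx) / (v + 1.0)
        ncy = (csum[s_id, 1] + ty) / (v + 1.0)
        ncz = (csum[s_id, 2] + tz) / (v + 1.0)
        for i in range(caf_ids.shape[0]):
            b = caf_ids[i]
            if b == s_id or vol[b] <= 0:
                continue
            vb = float(vol[b])
            bx = csum[b, 0] / vb
            by = csum[b, 1] / vb
            bz = csum[b, 2] / vb
            dn = np.sqrt((ncx - bx) ** 2 + (ncy - by) ** 2 + (ncz - bz) ** 2)
            do = np.sqrt((cx - bx) ** 2 + (cy - by) ** 2 + (cz - bz) ** 2)
            if dn < pp[6] and dn < do:
                dH += pp[7]

    return dH, ds_s, ds_t


@njit(cache=False)
def metropolis_accept(dH, temperature):
    """Boltzmann acceptance: certain for dH <= 0, exp(-dH/T) otherwise."""
    if dH <= 0.0:
        return True
    if temperature <= 0.0:
        return False
    return np.random.random() < np.exp(-dH / temperature)


@njit(cache=False, fastmath=True)
def mcs_sweep(grid, dens, kind, vol, surf, tvol, tsurf, csum, taxis_e, caf_ids,
              J, pp, n_attempts, n_dirs, rng_state):
    """One Monte Carlo step: ``n_attempts`` random voxel-copy attempts.

    Source voxels are drawn uniformly; the target is a uniform random face
    neighbour.  Copies across the domain boundary, into or out of the frozen
    air phase, and copies that would annihilate a cell's last voxel are
    rejected outright.  ``rng_state`` is a one-element uint64 xorshift64*
    state, updated in place.  Returns the number of accepted copies.
    """
    nx, ny, nz = grid.shape
    T = pp[2]
    accepted = 0
    ntot = nx * ny * nz
    span = float(ntot) * n_dirs
    state = rng_state[0]
    for _ in range(n_attempts):
        # one uniform draw picks both the source voxel and the direction
        state, r = _xorshift(state)
        u = int(r * span)
        d = u % n_dirs
        idx = u // n_dirs
        sz = idx % nz
        rem = idx // nz
        sy = rem % ny
        sx = rem // ny
        tx = sx + _DX6[d]
        ty = sy + _DY6[d]
        tz = sz + _DZ6[d]
        if tx < 0 or tx >= nx or ty < 0 or ty >= ny or tz < 0 or tz >= nz:
            continue
        s_id = grid[sx, sy, sz]
        t_id = grid[tx, ty, tz]
        if s_id == t_id:
            continue
        if s_id < 0 or t_id < 0:
            continue
        if t_id > 0 and vol[t_id] <= 1:
            continue
        dH, ds_s, ds_t = delta_h(grid, dens, kind, vol, surf, tvol, tsurf,
                                 csum, taxis_e, caf_ids, J, pp,
                                 sx, sy, sz, tx, ty, tz)
        if dH > 0.0:
            if T <= 0.0:
                continue
            state, r = _xorshift(state)
            if r >= np.exp(-dH / T):
                continue
        grid[tx, ty, tz] = s_id
        if s_id > 0:
            vol[s_id] += 1
            surf[s_id] += ds_s
            csum[s_id, 0] += tx
            csum[s_id, 1] += ty
            csum[s_id, 2] += tz
        if t_id > 0:
            vol[t_id] -= 1
            surf[t_id] += ds_t
            csum[t_id, 0] -= tx
            csum[t_id, 1] -= ty
            csum[t_id, 2] -= tz
        accepted += 1
    rng_state[0] = state
    return accepted


@njit(cache=False, fastmath=True)
def degrade_sweep(grid, dens, kind, rate_scc, rate_caf):
    """Multiplicative pericellular proteolysis.

    A matrix voxel adjacent to at least one cell of a kind is multiplied by
    (1 - rate_kind) this MCS; both factors apply when both kinds touch it.
    Residual density stored beneath a cell's own voxels is digested at the
    occupying cell's rate (membrane-bound protease acting on overlapped
    matrix), which is what turns a fibroblast's path into a permissive track
    rather than restoring intact matrix behind it.
    """
    if rate_scc <= 0.0 and rate_caf <= 0.0:
        return
    nx, ny, nz = grid.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if dens[x, y, z] <= 0.0:
                    continue
                occ = grid[x, y, z]
                if occ > 0:
                    r = rate_scc if kind[occ] == K_SCC else rate_caf
                    if r > 0.0:
                        dens[x, y, z] *= 1.0 - r
                    continue
                if occ != 0:
                    continue
                scc_adj = False
                caf_adj = False
                for k in range(6):
                    ax = x + _DX6[k]
                    ay = y + _DY6[k]
                    az = z + _DZ6[k]
                    if ax < 0 or ax >= nx or ay < 0 or ay >= ny or az < 0 or az >= nz:
                        continue
                    nid = grid[ax, ay, az]
                    if nid > 0:
                        if kind[nid] == K_SCC:
                            scc_adj = True
                        elif kind[nid] == K_CAF:
                            caf_adj = True
                f = 1.0
                if scc_adj:
                    f *= 1.0 - rate_scc
                if caf_adj:
                    f *= 1.0 - rate_caf
                if f < 1.0:
                    dens[x, y, z] *= f


@njit(cache=False)
def push_sweep(grid, dens, kind, vol, csum, rate_scc, rate_caf):
    """Mass-conserving matrix displacement away from pushing cells.

    A matrix voxel transfers fraction ``rate`` of its density per adjacent
    pushing-cell face along the outward normal (cell centroid -> voxel,
    quantised to the nearest lattice axis).  Receiving voxels clip at
    density 1; overflow continues outward; anything that cannot be placed
    anywhere outward returns to the source voxel, so total density is
    conserved exactly and stays within [0, 1].
    """
    if rate_scc <= 0.0 and rate_caf <= 0.0:
        return
    nx, ny, nz = grid.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if grid[x, y, z] != 0 or dens[x, y, z] <= 0.0:
                    continue
                for k in range(6):
                    ax = x + _DX6[k]
                    ay = y + _DY6[k]
                    az = z + _DZ6[k]
                    if ax < 0 or ax >= nx or ay < 0 or ay >= ny or az < 0 or az >= nz:
                        continue
                    cid = grid[ax, ay, az]
                    if cid <= 0:
                        continue
                    rate = rate_scc if kind[cid] == K_SCC else rate_caf
                    if rate <= 0.0:
                        continue
                    v = float(vol[cid])
                    vx = x - csum[cid, 0] / v
                    vy = y - csum[cid, 1] / v
                    vz = z - csum[cid, 2] / v
                    avx = abs(vx)
                    avy = abs(vy)
                    avz = abs(vz)
                    if avx == 0.0 and avy == 0.0 and avz == 0.0:
                        continue
                    sx = 0
                    sy = 0
                    sz = 0
                    if avx >= avy and avx >= avz:
                        sx = 1 if vx > 0 else -1
                    elif avy >= avz:
                        sy = 1 if vy > 0 else -1
                    else:
                        sz = 1 if vz > 0 else -1
                    amount = rate * dens[x, y, z]
                    if amount <= 0.0:
                        continue
                    dens[x, y, z] -= amount
                    rem = amount
                    cx, cy, cz = x, y, z
                    while rem > 1e-15:
                        cx += sx
                        cy += sy
                        cz += sz
                        if (cx < 0 or cx >= nx or cy < 0 or cy >= ny or
                                cz < 0 or cz >= nz or grid[cx, cy, cz] != 0):
                            # nowhere outward can take it: back to the origin,
                            # which has headroom for the amount just removed
                            dens[x, y, z] += rem
                            rem = 0.0
                            break
                        cap = 1.0 - dens[cx, cy, cz]
                        if cap > 0.0:
                            t = rem if rem < cap else cap
                            dens[cx, cy, cz] += t
                            rem -= t
                    # every adjacent pushing-cell face contributes this MCS
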