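"""Cellular Potts lattice, cell registry, and the Monte Carlo scheduler.

A :class:`Simulation` owns the 3D cell-id grid (0 = matrix/medium, -1 =
frozen air, >0 = cell), the per-voxel ECM density field, and incremental
per-cell bookkeeping (volume, exposed-face surface, centroid sums).  One
Monte Carlo step performs one copy attempt per lattice voxel, then applies
proteolysis, matrix displacement, and growth/mitosis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels
from .params import (AIR_ID, KIND_CAF, KIND_MEDIUM, KIND_SCC, SimParams)

__all__ = ["CueField", "Simulation", "compute_cell_geometry", "recount_geometry"]

_WALL = -2147483648  # out-of-bounds sentinel used in face counting


@dataclass(frozen=True)
class CueField:
    """Chemotactic cue: a uniform unit direction or a radial field.

    ``uniform`` cues bias copies along ``direction``; ``radial`` cues point
    outward from ``origin`` (spheroid centre), evaluated at the target voxel.
    """

    mode: str = "uniform"                 # "uniform" | "radial"
    direction: tuple = (0.0, 0.0, 1.0)    # unit vector for uniform cues
    origin: tuple = (0.0, 0.0, 0.0)       # centre for radial cues

    def __post_init__(self):
        if self.mode not in ("uniform", "radial"):
            raise ValueError(f"unknown cue mode {self.mode!r}")
        if self.mode == "uniform":
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("uniform cue needs a non-zero direction")
            object.__setattr__(self, "direction", tuple(d / n))


def recount_geometry(grid: np.ndarray, capacity: int):
    """Brute-force per-id (volume, surface, centroid-sum) from the grid.

    Surface counts exposed faces: faces adjoining a different id, the medium,
    air, or the domain wall.
    """
    vol = np.zeros(capacity, dtype=np.int64)
    surf = np.zeros(capacity, dtype=np.int64)
    csum = np.zeros((capacity, 3), dtype=np.float64)
    mask = grid > 0
    ids = grid[mask]
    if ids.size:
        vol[: ids.max() + 1] = np.bincount(ids)
        coords = np.nonzero(mask)
        for ax in range(3):
            np.add.at(csum[:, ax], ids, coords[ax].astype(np.float64))
    for axis in range(3):
        for sign in (1, -1):
            nbr = np.full_like(grid, _WALL)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            nbr[tuple(dst)] = grid[tuple(src)]
            exposed = mask & (grid != nbr)
            eids = grid[exposed]
            if eids.size:
                surf += np.bincount(eids, minlength=capacity)[:capacity]
    return vol, surf, csum


def compute_cell_geometry(grid: np.ndarray, cell_id: int):
    """(volume, surface, centroid) of one cell by direct recount.

    Raises ``KeyError`` for an id absent from the grid.
    """
    coords = np.argwhere(grid == cell_id)
    if coords.shape[0] == 0:
        raise KeyError(f"cell id {cell_id} not on the lattice")
    volume = coords.shape[0]
    lo = coords.min(axis=0) - 1
    hi = coords.max(axis=0) + 2
    pad_lo = np.maximum(-lo, 0)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.shape)
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub = np.pad(sub, [(pad_lo[i], 1) for i in range(3)], constant_values=_WALL)
    m = sub == cell_id
    surface = 0
    for axis in range(3):
        nbr = np.roll(sub, -1, axis=axis)
        surface += int(np.sum(m & (sub != nbr)))
        nbr = np.roll(sub, 1, axis=axis)
        surface += int(np.sum(m & (sub != nbr)))
    centroid = coords.mean(axis=0)
    return volume, surface, centroid


class Simulation:
    """One lattice simulation: state, parameters, cue, and the MCS loop."""

    def __init__(self, dims, params: SimParams, cue: CueField,
                 seed: int = 0, capacity: int = 2048,
                 caf_taxis_update_interval: int = 10):
        self.dims = tuple(int(d) for d in dims)
        self.params = params
        self.cue = cue
        self.seed = int(seed)
        self.grid = np.zeros(self.dims, dtype=np.int32)
        self.density = np.zeros(self.dims, dtype=np.float64)
        self.mcs_clock = 0
        self.caf_taxis_update_interval = int(caf_taxis_update_interval)
        self.interface = None  # set by scenario builders
        self._cap = int(capacity)
        self._alloc(self._cap)
        self.next_id = 1
        self._rng = np.random.default_rng(self.seed)
        self._rng_state = _kernels.make_rng_state(self.seed)
        _kernels.seed(self.seed % (2 ** 31))
        self._finalized = False
        self._n_attempts = None

    # ------------------------------------------------------------------ setup
    def _alloc(self, cap):
        self.kind = np.zeros(cap, dtype=np.int8)
        self.vol = np.zeros(cap, dtype=np.int64)
        self.surf = np.zeros(cap, dtype=np.int64)
        self.tvol = np.zeros(cap, dtype=np.float64)
        self.tsurf = np.zeros(cap, dtype=np.float64)
        self.csum = np.zeros((cap, 3), dtype=np.float64)
        self.taxis_e = np.zeros(cap, dtype=np.float64)
        self.mit_t0 = np.zeros(cap, dtype=np.float64)
        self.mit_interval = np.full(cap, np.inf, dtype=np.float64)

    def _grow_capacity(self):
        old = self._cap
        self._cap = old * 2
        for name in ("kind", "vol", "surf", "tvol", "tsurf", "taxis_e",
                     "mit_t0", "mit_interval"):
            arr = getattr(self, name)
            fill = np.inf if name == "mit_interval" else 0
            new = np.full(self._cap, fill, dtype=arr.dtype)
            new[:old] = arr
            setattr(self, name, new)
        new = np.zeros((self._cap, 3), dtype=np.float64)
        new[:old] = self.csum
        self.csum = new

    def add_cell(self, kind: int, voxels: np.ndarray) -> int:
        """Seed a new cell occupying ``voxels`` (an (n, 3) coordinate array).

        Seeding clears any matrix density at the occupied voxels (cells
        displace matrix when placed, they do not overlap it).
        """
        voxels = np.asarray(voxels, dtype=np.int64)
        if voxels.ndim != 2 or voxels.shape[1] != 3 or voxels.shape[0] == 0:
            raise ValueError("voxels must be a non-empty (n, 3) array")
        cid = self.next_id
        if cid >= self._cap:
            self._grow_capacity()
        self.next_id += 1
        idx = tuple(voxels.T)
        if np.any(self.grid[idx] != 0):
            raise ValueError("seed region overlaps an existing cell or air")
        self.grid[idx] = cid
        self.density[idx] = 0.0
        self.kind[cid] = kind
        p = self.params
        if kind == KIND_SCC:
            self.tvol[cid] = p.scc_initial_target_volume
            self.tsurf[cid] = p.scc_target_surface(self.tvol[cid])
            self.taxis_e[cid] = p.scc_taxis_gain * p.taxis_energy_scc
            self.mit_interval[cid] = self._draw_mitosis_interval()
            # seeded populations are asynchronous: random initial cycle phase
            if np.isfinite(self.mit_interval[cid]):
                phase = self._rng.uniform(0.0, self.mit_interval[cid])
                self.mit_t0[cid] = self.mcs_clock - phase
            else:
                self.mit_t0[cid] = self.mcs_clock
        else:
            self.tvol[cid] = p.caf_target_volume
            self.tsurf[cid] = p.caf_target_surface
            scale = (p.caf_taxis_override if p.caf_taxis_override is not None
                     else p.caf_taxis_min)
            self.taxis_e[cid] = p.caf_taxis_gain * scale
        return cid

    def _draw_mitosis_interval(self):
        mean = self.params.mean_time_to_mitosis
        t = self._rng.exponential(mean)
        return float(np.clip(t, 0.05 * mean, 3.0 * mean))

    def freeze_air(self, zmax: int):
        """Mark lattice layers z < zmax as the frozen air phase."""
        self.grid[:, :, :zmax] = AIR_ID
        self.density[:, :, :zmax] = 0.0

    def finalize(self):
        """Recount all cell geometry and lock in the attempt count per MCS."""
        vol, surf, csum = recount_geometry(self.grid, self._cap)
        self.vol = vol
        self.surf = surf
        self.csum = csum
        n_frozen = int(np.sum(self.grid == AIR_ID))
        self._n_attempts = int(np.prod(self.dims)) - n_frozen
        self._finalized = True
        self._refresh_caf_taxis()
        return self

    # --------------------------------------------------------------- plumbing
    def _pp(self):
        p = self.params
        pp = np.zeros(17, dtype=np.float64)
        pp[16] = p.ecm_entry_max_density
        pp[0] = p.lambda_volume
        pp[1] = p.lambda_surface
        pp[2] = p.temperature
        pp[3] = p.ecm_barrier
        pp[4] = p.j_scc_ecm
        pp[5] = p.j_scc_ecm_zero
        pp[6] = p.caf_repulsion_range
        pp[7] = p.caf_repulsion_penalty
        if self.cue.mode == "uniform":
            pp[8] = 0.0
            pp[9:12] = self.cue.direction
        else:
            pp[8] = 1.0
            pp[12:15] = self.cue.origin
        return pp

    def _caf_ids(self):
        ids = np.nonzero((self.kind == KIND_CAF) & (self.vol > 0))[0]
        return ids.astype(np.int64)

    @property
    def cell_ids(self):
        return np.nonzero(self.vol > 0)[0]

    @property
    def scc_ids(self):
        return np.nonzero((self.vol > 0) & (self.kind == KIND_SCC))[0]

    def centroids(self, ids=None):
        """Centroid coordinates (voxels) for the given (default: all) cells."""
        if ids is None:
            ids = self.cell_ids
        ids = np.asarray(ids)
        return self.csum[ids] / self.vol[ids, None]

    def cell_kinds(self):
        """Array mapping cell id -> kind code (0 where no cell)."""
        k = np.where(self.vol > 0, self.kind, 0)
        return k.astype(np.int8)

    # ------------------------------------------------------------- energetics
    def delta_hamiltonian(self, source, target):
        """Energy change for copying the id at ``source`` into ``target``.

        Both must be in-bounds lattice neighbours; the state is unmodified.
        """
        self._check_voxel(source)
        self._check_voxel(target)
        dH, _, _ = _kernels.delta_h(
            self.grid, self.density, self.kind, self.vol, self.surf,
            self.tvol, self.tsurf, self.csum, self.taxis_e, self._caf_ids(),
            self.params.contact_matrix(), self._pp(),
            source[0], source[1], source[2], target[0], target[1], target[2])
        return dH

    def _check_voxel(self, v):
        for i in range(3):
            if not (0 <= v[i] < self.dims[i]):
                raise IndexError(f"voxel {tuple(v)} outside lattice {self.dims}")

    def attempt_copy(self, source, target):
        """Single Metropolis copy attempt; returns True when accepted."""
        self._check_voxel(source)
        self._check_voxel(target)
        s_id = int(self.grid[tuple(source)])
        t_id = int(self.grid[tuple(target)])
        if s_id == t_id:
            return True  # dH = 0: accepted, nothing changes
        if s_id < 0 or t_id < 0:
            return False
        if t_id > 0 and self.vol[t_id] <= 1:
            return False  # would annihilate the cell's last voxel
        dH, ds_s, ds_t = _kernels.delta_h(
            self.grid, self.density, self.kind, self.vol, self.surf,
            self.tvol, self.tsurf, self.csum, self.taxis_e, self._caf_ids(),
            self.params.contact_matrix(), self._pp(),
            source[0], source[1], source[2], target[0], target[1], target[2])
        if not _kernels.metropolis_accept(dH, self.params.temperature):
            return False
        self.grid[tuple(target)] = s_id
        t = np.asarray(target, dtype=np.float64)
        if s_id > 0:
            self.vol[s_id] += 1
            self.surf[s_id] += ds_s
            self.csum[s_id] += t
        if t_id > 0:
            self.vol[t_id] -= 1
            self.surf[t_id] += ds_t
            self.csum[t_id] -= t
        return True

    # -------------------------------------------------------------- MCS loop
    def run_mcs(self, n: int = 1, record=None):
        """Advance the simulation by ``n`` Monte Carlo steps.

        ``record``: optional callable invoked as ``record(self)`` after each
        MCS (used for track sampling and cell-count time series).
        """
        if not self._finalized:
            raise RuntimeError("call finalize() after seeding cells")
        from .behaviors import grow_and_divide  # local import: avoid cycle
        p = self.params
        J = self.params.contact_matrix()
        for _ in range(int(n)):
            pp = self._pp()
            _kernels.mcs_sweep(
                self.grid, self.density, self.kind, self.vol, self.surf,
                self.tvol, self.tsurf, self.csum, self.taxis_e,
                self._caf_ids(), J, pp, self._n_attempts,
                self.params.copy_connectivity, self._rng_state)
            _kernels.degrade_sweep(self.grid, self.density, self.kind,
                                   p.degradation_rate_scc, p.degradation_rate_caf)
            _kernels.push_sweep(self.grid, self.density, self.kind, self.vol,
                                self.csum, p.pushing_rate_scc, p.pushing_rate_caf)
            grow_and_divide(self)
            self.mcs_clock += 1
            if self.mcs_clock % self.caf_taxis_update_interval == 0:
                self._refresh_caf_taxis()
            if record is not None:
                record(self)
        return self

    def _refresh_caf_taxis(self):
        """Set each CAF's taxis scale from its distance to the nearest SCC."""
        from .behaviors import caf_taxis_energy
        p = self.params
        cafs = self._caf_ids()
        if cafs.size == 0:
            return
        if p.caf_taxis_override is not None:
            self.taxis_e[cafs] = p.caf_taxis_gain * p.caf_taxis_override
            return
        kind_at = self.kind[np.clip(self.grid, 0, self._cap - 1)]
        scc_mask = (self.grid > 0) & (kind_at == KIND_SCC)
        if not scc_mask.any():
            self.taxis_e[cafs] = p.caf_taxis_gain * p.caf_taxis_min
            return
        dist = ndimage.distance_transform_edt(~scc_mask)
        cents = np.rint(self.centroids(cafs)).astype(int)
        for i, cid in enumerate(cafs):
            c = np.clip(cents[i], 0, np.asarray(self.dims) - 1)
            d = dist[tuple(c)]
            self.taxis_e[cid] = p.caf_taxis_gain * caf_taxis_energy(d, p)

    # ----------------------------------------------------------- consistency
    def checksum(self) -> int:
        """Order-independent fingerprint of the lattice state."""
        import zlib
        return zlib.crc32(self.grid.tobytes()) ^ zlib.crc32(
            np.round(self.density, 12).tobytes())

    def validate(self):
        """Assert registry bookkeeping equals a brute-force grid recount."""
        vol, surf, csum = recount_geometry(self.grid, self._cap)
        if not np.array_equal(vol, self.vol):
            raise AssertionError("cell volumes out of sync with grid")
        if not np.array_equal(surf, self.surf):
            raise AssertionError("cell surfaces out of sync with grid")
        if not np.allclose(csum, self.csum):
            raise AssertionError("centroid sums out of sync with grid")
        if self.density.min() < -1e-12 or self.density.max() > 1 + 1e-12:
            raise AssertionError("ECM density left [0, 1]")
        return True
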