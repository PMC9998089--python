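"""Directed motility, CAF interactions, SCC growth/mitosis, and speed
measurement.

Taxis is implemented as an energy bias on voxel-copy attempts (the standard
Potts convention): an extension of a motile cell along the local cue
direction is rewarded by -E cos(theta).  CAF taxis is stimulated by nearby
cancer cells, interpolating linearly from its maximum at contact down to its
minimum beyond the stimulation range.  SCC cells grow by ramping their
target volume and divide by a random plane through the centroid; CAFs do
not proliferate.
"""

from __future__ import annotations

import numpy as np

from .params import (KIND_SCC, SimParams, speed_voxels_per_mcs_to_um_per_min)


def scc_taxis_energy(direction, cue_direction, params: SimParams) -> float:
    """Taxis energy contribution -E cos(theta) for a proposed copy direction."""
    d = np.asarray(direction, dtype=float)
    u = np.asarray(cue_direction, dtype=float)
    dn = np.linalg.norm(d)
    un = np.linalg.norm(u)
    if dn == 0 or un == 0:
        return 0.0
    return -params.taxis_energy_scc * float(d @ u) / (dn * un)


def caf_taxis_energy(distance_to_scc: float, params: SimParams) -> float:
    """CAF taxis scale given the distance (voxels) to the nearest SCC surface.

    Maximum at contact, linear decay to the minimum at the stimulation range,
    constant minimum beyond (and when no cancer cell exists at all).
    """
    r = params.caf_taxis_range
    d = min(max(float(distance_to_scc), 0.0), r)
    return params.caf_taxis_max - (params.caf_taxis_max - params.caf_taxis_min) * d / r


def caf_repulsion_energy(separation_before: float, separation_after: float,
                         params: SimParams) -> float:
    """Penalty for a copy that moves two CAF centroids closer within range."""
    if separation_after < params.caf_repulsion_range and separation_after < separation_before:
        return params.caf_repulsion_penalty
    return 0.0


# --------------------------------------------------------------------- growth

def grow_and_divide(sim) -> list:
    """One MCS of SCC growth: ramp target volumes, split cells at the
    dividing volume.  Returns the list of (parent, daughter) id pairs.

    Each SCC ramps its target volume linearly from the initial to the
    dividing value over a per-cell stochastic mitosis interval (exponential
    jitter around the mean).  When the *actual* volume reaches the dividing
    volume the cell splits by a random plane through its centroid; both
    daughters restart the ramp.  Growth into matrix is implicitly limited by
    the ECM entry penalty, so confinement suppresses proliferation.
    """
    p = sim.params
    scc = sim.scc_ids
    if scc.size == 0:
        return []
    # the ramp continues past the dividing volume until the actual volume
    # catches up: interfacial pressure holds cells somewhat below target
    frac = np.clip((sim.mcs_clock - sim.mit_t0[scc]) / sim.mit_interval[scc], 0.0, 1.5)
    v0 = p.scc_initial_target_volume
    v1 = p.scc_dividing_volume
    sim.tvol[scc] = v0 + (v1 - v0) * frac
    sim.tsurf[scc] = p.scc_target_surface(sim.tvol[scc])
    ready = scc[sim.vol[scc] >= v1]
    events = []
    for cid in ready:
        did = _divide(sim, int(cid))
        if did is not None:
            events.append((int(cid), did))
    return events


def _divide(sim, cid: int):
    """Split cell ``cid`` by a random plane through its centroid."""
    coords = np.argwhere(sim.grid == cid)
    if coords.shape[0] < 2:
        return None
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    side = None
    for _ in range(8):
        n = sim._rng.normal(size=3)
        nn = np.linalg.norm(n)
        if nn == 0:
            continue
        proj = rel @ (n / nn)
        cand = proj > 0
        if 0 < cand.sum() < coords.shape[0]:
            side = cand
            break
    if side is None:  # degenerate geometry: split by rank instead
        order = np.argsort(rel @ np.array([1.0, 0.0, 0.0]))
        side = np.zeros(coords.shape[0], dtype=bool)
        side[order[coords.shape[0] // 2:]] = True
    new_coords = coords[side]
    new_id = sim.next_id
    if new_id >= sim._cap:
        sim._grow_capacity()
    sim.next_id += 1
    sim.grid[tuple(new_coords.T)] = new_id
    p = sim.params
    sim.kind[new_id] = KIND_SCC
    for i in (cid, new_id):
        from .engine import compute_cell_geometry
        v, s, c = compute_cell_geometry(sim.grid, i)
        sim.vol[i] = v
        sim.surf[i] = s
        sim.csum[i] = c * v
        sim.tvol[i] = p.scc_initial_target_volume
        sim.tsurf[i] = p.scc_target_surface(sim.tvol[i])
        sim.taxis_e[i] = p.taxis_energy_scc
        sim.mit_t0[i] = sim.mcs_clock
        sim.mit_interval[i] = sim._draw_mitosis_interval()
    return new_id


# ------------------------------------------------------------------ kinematics

def track_centroids(sim, n_mcs: int, interval: int, ids=None) -> np.ndarray:
    """Run the simulation recording centroids every ``interval`` MCS.

    Returns an array of shape (frames, n_cells, 3) in voxel coordinates,
    including the initial frame.  Cells are the ones alive at the start;
    divisions during tracking keep the parent id.
    """
    if ids is None:
        ids = sim.cell_ids.copy()
    ids = np.asarray(ids)
    frames = [sim.centroids(ids).copy()]
    steps = int(n_mcs) // int(interval)
    for _ in range(steps):
        sim.run_mcs(interval)
        frames.append(sim.centroids(ids).copy())
    return np.asarray(frames)


def median_speed(centroid_tracks: np.ndarray, interval_mcs: float) -> float:
    """Population median speed in microns/minute from centroid tracks.

    ``centroid_tracks``: (frames, cells, 3) voxel coordinates sampled every
    ``interval_mcs`` MCS.  Per cell, the median frame-to-frame displacement
    divided by the interval; the population median of those is converted at
    2 microns/voxel and 30 s/MCS.  Tracks with fewer than two frames are
    excluded.
    """
    tracks = np.asarray(centroid_tracks, dtype=float)
    if tracks.ndim != 3 or tracks.shape[0] < 2:
        raise ValueError("need at least two frames of (frames, cells, 3) tracks")
    steps = np.linalg.norm(np.diff(tracks, axis=0), axis=2)  # (frames-1, cells)
    per_cell = np.median(steps, axis=0) / float(interval_mcs)  # voxels / MCS
    return speed_voxels_per_mcs_to_um_per_min(float(np.median(per_cell)))
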