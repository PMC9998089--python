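"""Calibration experiments: single-cell speed and population volume.

These are the measurement protocols behind the model's calibration rows:
median speed of isolated cells under their taxis bias in unobstructed
medium, effective CAF speed through an intact matrix slab, and the median
cell volume of a growing wild-type population.  Centroid tracks are sampled
every 20 MCS (10-minute frames, matching time-lapse practice) and converted
at 2 microns/voxel and 30 s/MCS.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .behaviors import median_speed, track_centroids
from .engine import CueField, Simulation
from .params import KIND_CAF, KIND_SCC, SimParams

TRACK_INTERVAL_MCS = 20  # 10-minute sampling frames


def _no_growth(params: SimParams) -> SimParams:
    return dataclasses.replace(params, mean_time_to_mitosis=np.inf)


REMODELLED_DENSITY = 0.5  # representative density of remodelled, passable matrix


def isolated_cells_sim(kind: int, n_cells: int, params: SimParams, seed: int,
                       spacing: int = 14, medium_density: float | None = None,
                       hours: float = 4.0) -> Simulation:
    """Isolated cells migrating unobstructed along a uniform +x cue.

    Cancer cells are measured migrating through remodelled (passable,
    adhesive) matrix at density 0.5 — the environment they actually move
    through during invasion — while fibroblasts are measured in open
    medium, matching how each population's reference speed was obtained.
    ``medium_density`` overrides that default.  Cells are spaced far enough
    apart to stay non-interacting; growth is disabled.
    """
    if medium_density is None:
        medium_density = REMODELLED_DENSITY if kind == KIND_SCC else 0.0
    per_row = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / per_row))
    drift_room = int(np.ceil(hours * 120 * 0.08)) + 30
    nx = per_row * spacing + drift_room
    ny = n_rows * spacing + 4
    nz = 22
    sim = Simulation((nx, ny, nz), _no_growth(params),
                     CueField("uniform", direction=(1.0, 0.0, 0.0)), seed=seed)
    if medium_density > 0:
        sim.density[:] = medium_density
    placed = 0
    for i in range(per_row):
        for j in range(n_rows):
            if placed >= n_cells:
                break
            x0 = 2 + i * spacing
            y0 = 2 + j * spacing
            vox = np.mgrid[x0:x0 + 8, y0:y0 + 8, 7:15].reshape(3, -1).T
            sim.add_cell(kind, vox)
            placed += 1
    return sim.finalize()


def measure_median_speed(kind: int, n_cells: int, params: SimParams,
                         seed: int, hours: float = 4.0,
                         medium_density: float | None = None) -> float:
    """Population median speed (um/min) of isolated unobstructed cells."""
    sim = isolated_cells_sim(kind, n_cells, params, seed, hours=hours,
                             medium_density=medium_density)
    n_mcs = int(hours * 3600 / 30)
    tracks = track_centroids(sim, n_mcs, TRACK_INTERVAL_MCS)
    return median_speed(tracks, TRACK_INTERVAL_MCS)


def slab_sim(n_cafs: int, params: SimParams, seed: int,
             slab_start: int = 14, slab_thickness: int = 40,
             depth: int = 72) -> Simulation:
    """CAFs facing an intact density-1 matrix slab under a uniform +z cue.

    The slab has a free far side (as a real gel does): displaced matrix can
    compact toward it, which is what makes pushing-driven migration possible
    at all under exact mass conservation.
    """
    per_row = int(np.ceil(np.sqrt(n_cafs)))
    spacing = 16
    nx = per_row * spacing + 4
    ny = int(np.ceil(n_cafs / per_row)) * spacing + 4
    sim = Simulation((nx, ny, depth), _no_growth(params),
                     CueField("uniform", direction=(0.0, 0.0, 1.0)), seed=seed)
    sim.density[:, :, slab_start:slab_start + slab_thickness] = 1.0
    placed = 0
    for i in range(per_row):
        for j in range(int(np.ceil(n_cafs / per_row))):
            if placed >= n_cafs:
                break
            x0 = 2 + i * spacing
            y0 = 2 + j * spacing
            vox = np.mgrid[x0:x0 + 10, y0:y0 + 10, 4:12].reshape(3, -1).T
            sim.add_cell(KIND_CAF, vox)
            placed += 1
    return sim.finalize()


def measure_slab_speed(n_cafs: int, params: SimParams, seed: int,
                       hours: float = 16.0) -> float:
    """Effective median CAF speed (um/min) while remodelling into the slab."""
    sim = slab_sim(n_cafs, params, seed)
    n_mcs = int(hours * 3600 / 30)
    tracks = track_centroids(sim, n_mcs, TRACK_INTERVAL_MCS)
    return median_speed(tracks, TRACK_INTERVAL_MCS)


def colony_sim(n_cells: int, params: SimParams, seed: int,
               spacing: int = 10, dims=None) -> Simulation:
    """A small unconfined SCC colony with growth and mitosis active."""
    per_row = int(np.ceil(n_cells ** (1 / 3)))
    if dims is None:
        side = max(40, per_row * spacing + 24)
        dims = (side, side, side)
    sim = Simulation(dims, params,
                     CueField("uniform", direction=(0.0, 0.0, 1.0)), seed=seed)
    placed = 0
    off = (np.asarray(dims) - per_row * spacing) // 2
    for i in range(per_row):
        for j in range(per_row):
            for k in range(per_row):
                if placed >= n_cells:
                    break
                x0, y0, z0 = (off + np.array([i, j, k]) * spacing).astype(int)
                vox = np.mgrid[x0:x0 + 8, y0:y0 + 8, z0:z0 + 8].reshape(3, -1).T
                sim.add_cell(KIND_SCC, vox)
                placed += 1
    return sim.finalize()


def measure_median_volume(n_cells: int, params: SimParams, seed: int,
                          days: float = 2.0) -> float:
    """Median SCC volume (voxels) after growing a colony for some days."""
    sim = colony_sim(n_cells, params, seed)
    sim.run_mcs(int(days * 24 * 3600 / 30))
    return float(np.median(sim.vol[sim.scc_ids]))
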