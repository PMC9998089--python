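"""Synthetic labelled volumes with constructively known invasion metrics.

These generators emulate what the engine emits — a 3D cell-id grid, an
id -> kind lookup, an interface record and an ECM density channel — from
hand-placed geometry, so every metric can be exercised and cross-checked
without running the Monte Carlo engine.  Each generator returns the state
plus a sidecar dict of expected values derived from the construction (cube
positions and counts), never from the metric implementations themselves.
"""

from __future__ import annotations

import numpy as np

from .params import KIND_CAF, KIND_SCC


def place_cube(grid: np.ndarray, cell_id: int, corner, size) -> None:
    """Fill an axis-aligned cube of ``size`` voxels per side with ``cell_id``."""
    x, y, z = corner
    s = size
    if np.any(np.asarray(corner) < 0) or np.any(np.asarray(corner) + s > grid.shape):
        raise ValueError("cube outside the volume")
    grid[x:x + s, y:y + s, z:z + s] = cell_id


def labelled_volume(dims, cells):
    """Build (grid, kinds) from a list of (kind, corner, size) cube specs."""
    grid = np.zeros(tuple(dims), dtype=np.int32)
    kinds = np.zeros(len(cells) + 1, dtype=np.int8)
    for i, (kind, corner, size) in enumerate(cells, start=1):
        place_cube(grid, i, corner, size)
        kinds[i] = kind
    return grid, kinds


def invasion_depth_fixture(depths=(10, 20, 30), size=5, dims=(48, 48, 48),
                           interface_z=6):
    """Cells whose centroids sit at prescribed depths beyond a plane.

    Returns (grid, kinds, interface, density, expected) where the expected
    max invasion and invasion score follow directly from the placed depths:
    score = n_cells * mean(depth).
    """
    cells = []
    half = (size - 1) / 2.0
    for i, d in enumerate(depths):
        zc = interface_z + d
        corner = (4 + i * (size + 2), 4, int(round(zc - half)))
        cells.append((KIND_SCC, corner, size))
    grid, kinds = labelled_volume(dims, cells)
    interface = {"type": "plane", "z": interface_z}
    density = np.ones(tuple(dims))
    density[grid > 0] = 0.0
    expected = {
        "max_invasion": float(max(depths)) if depths else 0.0,
        "invasion_score": float(len(depths) * np.mean(depths)) if depths else 0.0,
        "distances": [float(d) for d in depths],
    }
    return grid, kinds, interface, density, expected


def touching_pair_fixture(dims=(24, 24, 24), size=4, interface_z=2):
    """Two face-touching invasive SCC cubes: each has exactly one neighbour."""
    corner_a = (8, 8, 10)
    corner_b = (8 + size, 8, 10)
    grid, kinds = labelled_volume(dims, [(KIND_SCC, corner_a, size),
                                         (KIND_SCC, corner_b, size)])
    interface = {"type": "plane", "z": interface_z}
    expected = {"mean_neighbours": 1.0}
    return grid, kinds, interface, expected


def fragmented_fixture(n_fragments=1, caf_only_fragments=0, dims=(48, 32, 32)):
    """A bulk SCC mass plus detached cell clusters.

    Only detached clusters containing an SCC count as fractured objects.
    """
    cells = [(KIND_SCC, (2, 2, 2), 8), (KIND_SCC, (10, 2, 2), 8)]  # bulk: two touching
    x = 24
    for _ in range(n_fragments):
        cells.append((KIND_SCC, (x, 4, 4), 4))
        x += 7
    for _ in range(caf_only_fragments):
        cells.append((KIND_CAF, (x, 4, 4), 4))
        x += 7
    grid, kinds = labelled_volume(dims, cells)
    expected = {"fractured_objects": int(n_fragments)}
    return grid, kinds, expected


def hollow_fixture(dims=(48, 48, 48), n_shards=8, shard=4):
    """Equal detached shards with no dominant mass: the hollow/broken case."""
    cells = []
    positions = [(4 + 10 * (i % 4), 4 + 10 * (i // 4), 20) for i in range(n_shards)]
    for pos in positions:
        cells.append((KIND_SCC, pos, shard))
    grid, kinds = labelled_volume(dims, cells)
    expected = {"excluded": True}
    return grid, kinds, expected


def track_density_fixture(qualifying=((5, 0.5), (7, 0.2)), dims=(16, 16, 32),
                          interface_z=4):
    """Density field with chosen qualifying voxels beyond the boundary.

    ``qualifying`` lists (depth_beyond_boundary, density <= 0.75) voxels;
    the expected linearly weighted score is the sum of the depths.
    """
    density = np.ones(tuple(dims))
    grid = np.zeros(tuple(dims), dtype=np.int32)
    for i, (depth, rho) in enumerate(qualifying):
        density[4 + i, 4, interface_z + depth] = rho
    interface = {"type": "plane", "z": interface_z}
    expected = {"track_invasion_score": float(sum(d for d, _ in qualifying))}
    return grid, density, interface, expected


def spherical_front_fixture(radius=90, dims=(160, 160, 104), interface_z=4):
    """A dome-shaped invasive front of known curvature.

    The radius exceeds the half-width of the domain, so the mid-plane
    leading edge is a circular arc of the given radius everywhere and the
    expected mean curvature is 1/radius.
    """
    nx, ny, nz = dims
    cx, cy = nx / 2.0, ny / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    dome = (x - cx) ** 2 + (y - cy) ** 2 + (z - interface_z) ** 2 <= radius ** 2
    dome &= z >= interface_z
    grid = np.where(dome, 1, 0).astype(np.int32)
    grid[:, :, :interface_z + 1] = 1  # attach the dome to a base slab
    kinds = np.array([0, KIND_SCC], dtype=np.int8)
    interface = {"type": "plane", "z": interface_z}
    expected = {"curvature": 1.0 / radius}
    return grid, kinds, interface, expected
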