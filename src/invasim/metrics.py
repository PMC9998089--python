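"""Invasion quantification from labelled cell-id volumes and ECM density.

All metrics operate on plain arrays (a 3D integer cell-id grid, an id->kind
lookup, an interface record, and optionally the density field), so they can
be computed on engine snapshots or on synthetic labelled volumes alike.
Distances are in voxels.  The interface record is either
``{"type": "plane", "z": z0}`` (slab geometries; perpendicular distance) or
``{"type": "sphere", "center": c, "radius": r0}`` (radial distance beyond
the initial spheroid surface).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import KIND_SCC

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MetricsRecord:
    """The invasion metric suite for one run."""

    max_invasion: float = 0.0
    invasion_score: float = 0.0
    mean_neighbours: float = 0.0
    tapering: float = float("nan")
    fractured_objects: int = 0
    growth_rate: float = float("nan")
    track_invasion_score: float = float("nan")
    track_width: float = float("nan")
    curvature: float = float("nan")
    excluded: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ------------------------------------------------------------------ plumbing

def _centroids_by_id(grid: np.ndarray):
    """id -> centroid (voxels) for every positive id on the grid."""
    mask = grid > 0
    ids = grid[mask]
    if ids.size == 0:
        return np.zeros(0, dtype=int), np.zeros((0, 3))
    n = ids.max() + 1
    counts = np.bincount(ids, minlength=n)
    coords = np.nonzero(mask)
    cents = np.zeros((n, 3))
    for ax in range(3):
        cents[:, ax] = np.bincount(ids, weights=coords[ax], minlength=n)
    present = np.nonzero(counts)[0]
    cents[present] /= counts[present, None]
    return present, cents


def _distance_beyond(points: np.ndarray, interface: dict) -> np.ndarray:
    """Signed distance of points beyond the initial tumour interface."""
    points = np.atleast_2d(points)
    if interface["type"] == "plane":
        return points[:, 2] - float(interface["z"])
    if interface["type"] == "sphere":
        c = np.asarray(interface["center"], dtype=float)
        return np.linalg.norm(points - c, axis=1) - float(interface["radius"])
    raise ValueError(f"unknown interface type {interface['type']!r}")


def _adjacency_pairs(grid: np.ndarray):
    """Unique unordered pairs of distinct positive ids sharing a voxel face."""
    pairs = []
    for axis in range(3):
        a = np.moveaxis(grid, axis, 0)[:-1].ravel()
        b = np.moveaxis(grid, axis, 0)[1:].ravel()
        m = (a > 0) & (b > 0) & (a != b)
        if m.any():
            p = np.stack([a[m], b[m]], axis=1)
            pairs.append(np.sort(p, axis=1))
    if not pairs:
        return np.zeros((0, 2), dtype=grid.dtype)
    return np.unique(np.concatenate(pairs, axis=0), axis=0)


def _bulk_label(grid: np.ndarray, kinds: np.ndarray):
    """(labels, bulk_label_id): 26-connected components of all cell voxels;
    the bulk tumour mass is the largest component containing an SCC voxel.
    Returns bulk_label_id 0 when no SCC-containing component exists."""
    labels, n = ndimage.label(grid > 0, structure=_STRUCT26)
    if n == 0:
        return labels, 0
    scc_mask = _scc_voxel_mask(grid, kinds)
    best, best_size = 0, -1
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    has_scc = np.zeros(n + 1, dtype=bool)
    if scc_mask.any():
        has_scc[np.unique(labels[scc_mask])] = True
    for lab in range(1, n + 1):
        if has_scc[lab] and sizes[lab] > best_size:
            best, best_size = lab, sizes[lab]
    return labels, best


def _scc_voxel_mask(grid: np.ndarray, kinds: np.ndarray) -> np.ndarray:
    kinds = np.asarray(kinds)
    lookup = kinds[np.clip(grid, 0, kinds.size - 1)]
    return (grid > 0) & (lookup == KIND_SCC)


# ------------------------------------------------------------------- metrics

def identify_invasive_cells(grid: np.ndarray, kinds: np.ndarray, interface: dict):
    """Invasive SCC ids and their distances beyond the interface.

    A cell is invasive when its centroid lies strictly beyond the interface
    recorded at build time (a centroid exactly on the interface is not).
    """
    if interface is None:
        raise ValueError("no interface recorded for this state")
    ids, cents = _centroids_by_id(grid)
    kinds = np.asarray(kinds)
    scc = ids[kinds[ids] == KIND_SCC]
    if scc.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    d = _distance_beyond(cents[scc], interface)
    inv = d > 0
    return scc[inv], d[inv]


def invasion_metrics_basic(grid: np.ndarray, kinds: np.ndarray, interface: dict):
    """(max_invasion, invasion_score).

    The invasion score is the number of invasive cells multiplied by the
    mean distance of their centroids beyond the interface; both are 0 when
    nothing has invaded.
    """
    _, d = identify_invasive_cells(grid, kinds, interface)
    if d.size == 0:
        return 0.0, 0.0
    return float(d.max()), float(d.size * d.mean())


def neighbour_and_tapering(grid: np.ndarray, kinds: np.ndarray, interface: dict):
    """(mean_neighbours, tapering) over invasive SCCs in the bulk tumour mass.

    Neighbours are SCC cells sharing at least one voxel face.  Tapering is
    the ordinary-least-squares slope of neighbour count against distance
    beyond the interface; it is NaN when fewer than two distinct distances
    exist.  With no invading bulk mass the mean neighbour count is 0.
    """
    inv_ids, dists = identify_invasive_cells(grid, kinds, interface)
    if inv_ids.size == 0:
        return 0.0, float("nan")
    labels, bulk = _bulk_label(grid, kinds)
    if bulk == 0:
        return 0.0, float("nan")
    # a cell belongs to the component holding its first voxel
    in_bulk = []
    for cid in inv_ids:
        vox = np.argwhere(grid == cid)[0]
        in_bulk.append(labels[tuple(vox)] == bulk)
    in_bulk = np.asarray(in_bulk, dtype=bool)
    ids = inv_ids[in_bulk]
    dists = dists[in_bulk]
    if ids.size == 0:
        return 0.0, float("nan")
    pairs = _adjacency_pairs(grid)
    kinds = np.asarray(kinds)
    if pairs.size:
        scc_pairs = pairs[(kinds[pairs[:, 0]] == KIND_SCC) &
                          (kinds[pairs[:, 1]] == KIND_SCC)]
    else:
        scc_pairs = pairs
    ncount = np.zeros(int(grid.max()) + 1)
    for a, b in scc_pairs:
        ncount[a] += 1
        ncount[b] += 1
    neighbours = ncount[ids]
    mean_nb = float(neighbours.mean())
    if np.unique(dists).size < 2:
        return mean_nb, float("nan")
    slope = np.polyfit(dists, neighbours, 1)[0]
    return mean_nb, float(slope)


def fractured_objects(grid: np.ndarray, kinds: np.ndarray) -> int:
    """Number of 26-connected cell objects, detached from the bulk tumour
    mass, that contain at least one SCC voxel."""
    labels, bulk = _bulk_label(grid, kinds)
    n = labels.max()
    if n == 0:
        return 0
    scc_mask = _scc_voxel_mask(grid, kinds)
    if not scc_mask.any():
        return 0
    scc_labels = np.unique(labels[scc_mask])
    return int(np.sum(scc_labels != bulk))


def growth_fit(times_mcs, scc_counts) -> float:
    """Exponential growth rate (per day) from an SCC-count time series.

    Least-squares fit of log(count) against time; points with zero counts
    are excluded.  Requires at least two usable timepoints.
    """
    from .params import mcs_to_days
    t = np.asarray(times_mcs, dtype=float)
    c = np.asarray(scc_counts, dtype=float)
    keep = c > 0
    t, c = t[keep], c[keep]
    if t.size < 2:
        raise ValueError("need at least two non-zero timepoints")
    days = np.array([mcs_to_days(x) for x in t])
    slope = np.polyfit(days, np.log(c), 1)[0]
    return float(slope)


def track_invasion_score(density: np.ndarray, grid: np.ndarray,
                         interface: dict, threshold: float = 0.75,
                         region: np.ndarray | None = None) -> float:
    """Distance-weighted sum of remodelled matrix beyond the interface.

    Every voxel beyond the initial tumour boundary whose ECM density is at
    or below ``threshold`` contributes its distance beyond the boundary
    (linear weighting).  Voxels currently occupied by cells contribute with
    the residual density stored beneath them.  ``region`` (for example
    :func:`invasim.ecm.track_region`) restricts scoring to the
    neighbourhood around a permissive track.  For spheroids the radial
    distance quantifies both sides of the initial mass.
    """
    qual = (density <= threshold) & (grid >= 0)
    if region is not None:
        qual &= region
    coords = np.argwhere(qual)
    if coords.size == 0:
        return 0.0
    d = _distance_beyond(coords.astype(float), interface)
    return float(d[d > 0].sum())


def front_profile_curvature(profile: np.ndarray, window: int = 50) -> float:
    """Mean point-wise curvature of a 1D front profile.

    The profile is smoothed with a moving-average window (reflected
    boundaries) and the curvature of each interior point is estimated from
    the circumcircle through it and its two neighbours; the mean magnitude
    is returned (exact 1/r on a circular arc).
    """
    h = np.asarray(profile, dtype=float)
    if h.size < 3:
        raise ValueError("profile too short for curvature")
    w = max(1, min(int(window), h.size))
    # odd reflection continues the boundary slope instead of folding it
    # back, which would fabricate curvature at the profile ends
    padded = np.pad(h, w, mode="reflect", reflect_type="odd")
    kernel = np.ones(w) / w
    smooth = np.convolve(padded, kernel, mode="same")[w:-w]
    x = np.arange(h.size, dtype=float)
    a = np.stack([x[:-2], smooth[:-2]], axis=1)
    b = np.stack([x[1:-1], smooth[1:-1]], axis=1)
    c = np.stack([x[2:], smooth[2:]], axis=1)
    ab = b - a
    bc = c - b
    ca = a - c
    cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
    area2 = np.abs(cross)  # 2 * triangle area
    la = np.linalg.norm(ab, axis=1)
    lb = np.linalg.norm(bc, axis=1)
    lc = np.linalg.norm(ca, axis=1)
    denom = la * lb * lc
    k = np.where(denom > 0, 2.0 * area2 / np.where(denom > 0, denom, 1.0), 0.0)
    return float(k.mean())


def front_height_map(grid: np.ndarray, interface: dict) -> np.ndarray:
    """Leading-edge depth z(x, y): deepest cell voxel per column, or the
    interface plane where the column holds no cells."""
    if interface["type"] != "plane":
        raise ValueError("front extraction needs a planar interface")
    z0 = int(interface["z"])
    nz = grid.shape[2]
    cells = grid > 0
    zidx = np.arange(nz)
    depth = np.where(cells, zidx[None, None, :], -1).max(axis=2)
    return np.maximum(depth, z0).astype(float)


def track_width_and_curvature(grid: np.ndarray, kinds: np.ndarray,
                              interface: dict, window: int = 50,
                              uniform_fraction: float = 0.9):
    """(track_width, curvature) of the invading strand / leading front.

    Width is the maximum cross-section extent (perpendicular to the cue
    axis) of the largest connected strand beyond the interface.  Strands
    that are non-invasive, or where the whole mass has advanced uniformly
    (cross-section occupancy above ``uniform_fraction``), record NaN.
    Curvature averages the smoothed mid-plane x-z and y-z front profiles.
    """
    if interface["type"] != "plane":
        raise ValueError("strand width/curvature are defined for slab geometries")
    z0 = int(interface["z"])
    beyond = np.zeros_like(grid, dtype=bool)
    beyond[:, :, z0 + 1:] = grid[:, :, z0 + 1:] > 0
    width = float("nan")
    if beyond.any():
        labels, n = ndimage.label(beyond, structure=_STRUCT26)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        strand = labels == sizes.argmax()
        occupancy = strand[:, :, z0 + 1].mean() if grid.shape[2] > z0 + 1 else 0.0
        if occupancy < uniform_fraction:
            extents = []
            for z in range(z0 + 1, grid.shape[2]):
                sl = strand[:, :, z]
                if not sl.any():
                    continue
                xs, ys = np.nonzero(sl)
                extents.append(max(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1))
            if extents:
                width = float(max(extents))
    hm = front_height_map(grid, interface)
    prof_x = hm[:, hm.shape[1] // 2]
    prof_y = hm[hm.shape[0] // 2, :]
    curv = 0.5 * (front_profile_curvature(prof_x, window) +
                  front_profile_curvature(prof_y, window))
    return width, curv


def hollow_exclusion(grid: np.ndarray, kinds: np.ndarray,
                     min_bulk_fraction: float = 0.5) -> bool:
    """Flag runs whose largest SCC-containing object holds less than
    ``min_bulk_fraction`` of all SCC voxels (hollow / broken-apart masses)."""
    scc_mask = _scc_voxel_mask(grid, kinds)
    total = int(scc_mask.sum())
    if total == 0:
        return True
    labels, n = ndimage.label(grid > 0, structure=_STRUCT26)
    scc_per_label = np.bincount(labels[scc_mask].ravel(), minlength=n + 1)
    return bool(scc_per_label.max() < min_bulk_fraction * total)


def compute_record(sim, counts_times=None, counts=None,
                   with_track: bool = False, with_front: bool = False,
                   curvature_window: int = 50) -> MetricsRecord:
    """Compute the full metric suite from a live simulation."""
    grid = sim.grid
    kinds = sim.cell_kinds()
    interface = sim.interface
    rec = MetricsRecord()
    rec.max_invasion, rec.invasion_score = invasion_metrics_basic(grid, kinds, interface)
    rec.mean_neighbours, rec.tapering = neighbour_and_tapering(grid, kinds, interface)
    rec.fractured_objects = fractured_objects(grid, kinds)
    if counts_times is not None and counts is not None and len(counts) >= 2:
        try:
            rec.growth_rate = growth_fit(counts_times, counts)
        except ValueError:
            pass
    if with_track:
        rec.track_invasion_score = track_invasion_score(sim.density, grid, interface)
    if with_front and interface["type"] == "plane":
        rec.track_width, rec.curvature = track_width_and_curvature(
            grid, kinds, interface, window=curvature_window)
    if sim.interface["type"] == "sphere":
        rec.excluded = hollow_exclusion(grid, kinds)
    return rec
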