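"""Continuous ECM density field: proteolysis, displacement, entry energetics,
and texture builders.

Density lives in [0, 1] per voxel (1 = intact matrix).  Cells occupy voxels
without destroying the residual density stored there: proteolysis and
displacement are the only mechanisms that permanently remove or relocate
matrix.  Degradation is multiplicative per MCS; displacement ("pushing")
conserves total density exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import KIND_SCC, SimParams


@dataclass(frozen=True)
class TextureSpec:
    """Descriptor for an initial ECM texture.

    kind: "uniform" | "single_track" | "parallel_fibres" | "chessboard".
    ``track_cross_section`` is the (x, y) cross-section of a permissive
    track running along the cue (z) axis; ``period`` is the plane/cube
    period of fibre or chessboard textures; ``low``/``high`` are the two
    density levels; ``axis`` orients fibre planes (normal axis, 0=x, 1=y).
    """

    kind: str = "uniform"
    track_cross_section: tuple = (6, 6)
    period: int = 8
    low: float = 0.0
    high: float = 1.0
    axis: int = 0


def degrade(density: np.ndarray, grid: np.ndarray, kinds: np.ndarray,
            params: SimParams) -> np.ndarray:
    """Apply one MCS of proteolysis in place and return the field.

    Every matrix voxel face-adjacent to a cell of kind k is multiplied by
    (1 - rate_k); both factors apply when both kinds are adjacent.
    """
    _kernels.degrade_sweep(grid, density, kinds,
                           params.degradation_rate_scc,
                           params.degradation_rate_caf)
    return density


def push(density: np.ndarray, grid: np.ndarray, kinds: np.ndarray,
         vol: np.ndarray, csum: np.ndarray, params: SimParams) -> np.ndarray:
    """Apply one MCS of mass-conserving matrix displacement in place."""
    _kernels.push_sweep(grid, density, kinds, vol, csum,
                        params.pushing_rate_scc, params.pushing_rate_caf)
    return density


def ecm_entry_penalty(density: float, mover_kind: int, params: SimParams):
    """(contact_energy, barrier) for a cell extending into a matrix voxel.

    The contact component interpolates linearly between the full-density and
    zero-density SCC-matrix energies; the barrier is proportional to the
    residual density, so intact matrix resists entry and fully degraded
    voxels cost only the zero-density contact energy.
    """
    if not (0.0 <= density <= 1.0):
        raise ValueError(f"density {density} outside [0, 1]")
    if mover_kind == KIND_SCC:
        contact = params.j_scc_ecm_zero + (params.j_scc_ecm - params.j_scc_ecm_zero) * density
    else:
        contact = params.j_caf_ecm
    barrier = params.ecm_barrier * density
    return contact, barrier


def track_region(spec: TextureSpec, dims, margin: int = 4) -> np.ndarray:
    """Boolean mask of the neighbourhood around a permissive track.

    The track's cross-section footprint, dilated laterally by ``margin``
    voxels, over the full cue axis; used to restrict the track invasion
    score to remodelling around the track.
    """
    if spec.kind != "single_track":
        raise ValueError("track region is defined for single_track textures")
    dims = tuple(int(d) for d in dims)
    a, b = spec.track_cross_section
    x0 = (dims[0] - a) // 2
    y0 = (dims[1] - b) // 2
    mask = np.zeros(dims, dtype=bool)
    mask[max(0, x0 - margin):x0 + a + margin,
         max(0, y0 - margin):y0 + b + margin, :] = True
    return mask


def build_texture(spec: TextureSpec, dims) -> np.ndarray:
    """Construct an initial density field for the given texture descriptor."""
    dims = tuple(int(d) for d in dims)
    if spec.kind == "uniform":
        return np.full(dims, spec.high, dtype=np.float64)
    if spec.kind == "single_track":
        a, b = spec.track_cross_section
        if a > dims[0] or b > dims[1]:
            raise ValueError("track cross-section wider than the domain")
        field = np.full(dims, spec.high, dtype=np.float64)
        x0 = (dims[0] - a) // 2
        y0 = (dims[1] - b) // 2
        field[x0:x0 + a, y0:y0 + b, :] = spec.low
        return field
    if spec.kind == "parallel_fibres":
        # alternating low/high planes whose normal is `axis`, fibres run along z
        coords = np.arange(dims[spec.axis])
        stripe = (coords // spec.period) % 2 == 0
        field = np.where(stripe, spec.low, spec.high).astype(np.float64)
        shape = [1, 1, 1]
        shape[spec.axis] = dims[spec.axis]
        return np.broadcast_to(field.reshape(shape), dims).copy()
    if spec.kind == "chessboard":
        x, y, z = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
        parity = ((x // spec.period) + (y // spec.period) + (z // spec.period)) % 2
        return np.where(parity == 0, spec.low, spec.high).astype(np.float64)
    raise ValueError(f"unknown texture kind {spec.kind!r}")
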