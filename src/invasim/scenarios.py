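"""Constructors for the simulation geometries.

Three families:

* organotypic — a cancer-cell monolayer on top of an intact matrix slab,
  with a frozen air phase above (gas-liquid interface) and a uniform cue
  pointing down into the matrix; fibroblasts, when present, are dispersed
  in the slab or mixed into the cell layer.
* spheroid — a cell mass (optionally mixed 1:1 with fibroblasts, matching
  the experimental hanging-drop ratio) encapsulated in intact matrix, with
  a radial outward cue (uniform-cue variant available).
* front_curvature — a cancer-cell slab facing matrix under a uniform cue,
  without fibroblasts, used to quantify the shape of the invading front;
  supports permissive-track and fibre/chessboard textures.

The z axis increases with invasion depth in the slab geometries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .ecm import TextureSpec, build_texture
from .engine import CueField, Simulation
from .params import DAY4_MCS, KIND_CAF, KIND_SCC, SimParams


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one simulation setup."""

    geometry: str = "organotypic"   # organotypic | spheroid | front_curvature
    dims: tuple = (64, 64, 64)
    n_caf: int = 0
    caf_placement: str = "matrix"   # "matrix" | "mixed"
    caf_fraction: float = 0.5       # spheroid: fraction of seeded blocks that are CAFs
    cue: str = "default"            # organotypic/front: uniform; spheroid: radial|uniform
    texture: TextureSpec = field(default_factory=TextureSpec)
    cell_layer_thickness: int = 8
    air_thickness: int = 3
    spheroid_radius: int = 14
    # perturbation multipliers relative to wild type
    proteolysis: float = 1.0
    scc_scc_adhesion: float = 1.0
    scc_ecm_adhesion: float = 1.0
    growth: float = 1.0
    duration_mcs: int = DAY4_MCS
    seed: int = 0

    def scaled_params(self, base: SimParams | None = None) -> SimParams:
        base = base if base is not None else SimParams()
        return base.with_multipliers(
            proteolysis=self.proteolysis,
            scc_scc_adhesion=self.scc_scc_adhesion,
            scc_ecm_adhesion=self.scc_ecm_adhesion,
            growth=self.growth,
        )


def _tile_blocks(x_range, y_range, z_range, block):
    """Non-overlapping block origins tiling a cuboid region."""
    bx, by, bz = block
    origins = []
    for x in range(x_range[0], x_range[1] - bx + 1, bx):
        for y in range(y_range[0], y_range[1] - by + 1, by):
            for z in range(z_range[0], z_range[1] - bz + 1, bz):
                origins.append((x, y, z))
    return origins


def _block_voxels(origin, block):
    x, y, z = origin
    bx, by, bz = block
    g = np.mgrid[x:x + bx, y:y + by, z:z + bz]
    return g.reshape(3, -1).T


def build_organotypic(config: ScenarioConfig, params: SimParams | None = None) -> Simulation:
    """Monolayer-on-slab geometry with a uniform downward cue."""
    nx, ny, nz = config.dims
    air = config.air_thickness
    layer = config.cell_layer_thickness
    interface_z = air + layer
    if interface_z + 8 > nz:
        raise ValueError("domain too shallow for cell layer plus matrix slab")
    params = config.scaled_params(params)
    cue = CueField("uniform", direction=(0.0, 0.0, 1.0))
    sim = Simulation(config.dims, params, cue, seed=config.seed)
    sim.freeze_air(air)
    # matrix slab (with texture) below the future cell layer
    tex = build_texture(config.texture, config.dims)
    sim.density[:, :, interface_z:] = tex[:, :, interface_z:]
    rng = np.random.default_rng(config.seed)
    # cancer cell monolayer: 8x8 blocks across the full cross-section
    block = (8, 8, layer)
    origins = _tile_blocks((0, nx), (0, ny), (air, interface_z), block)
    caf_mixed = []
    if config.n_caf and config.caf_placement == "mixed":
        caf_mixed = list(rng.choice(len(origins), size=min(config.n_caf, len(origins)),
                                    replace=False))
    for i, origin in enumerate(origins):
        kind = KIND_CAF if i in caf_mixed else KIND_SCC
        sim.add_cell(kind, _block_voxels(origin, block))
    # fibroblasts dispersed in the upper slab, where they can lead invasion
    # from the tumour-matrix interface downward
    if config.n_caf and config.caf_placement == "matrix":
        _scatter_cafs(sim, rng, config.n_caf,
                      z_range=(interface_z, min(interface_z + 16, nz - 10)))
    sim.interface = {"type": "plane", "z": interface_z}
    return sim.finalize()


def _scatter_cafs(sim, rng, n, z_range):
    """Place CAF seed blocks (10x10x8 = 800 voxels) at random free spots."""
    nx, ny, nz = sim.dims
    block = (10, 10, 8)
    placed = 0
    for _ in range(200 * n):
        if placed >= n:
            break
        x = int(rng.integers(0, nx - block[0] + 1))
        y = int(rng.integers(0, ny - block[1] + 1))
        zlo, zhi = z_range
        if zhi - block[2] < zlo:
            raise ValueError("matrix slab too thin for fibroblast seeds")
        z = int(rng.integers(zlo, zhi - block[2] + 1))
        region = sim.grid[x:x + block[0], y:y + block[1], z:z + block[2]]
        if np.any(region != 0):
            continue
        sim.add_cell(KIND_CAF, _block_voxels((x, y, z), block))
        placed += 1
    if placed < n:
        raise ValueError(f"could not place {n} fibroblasts (placed {placed})")


def build_spheroid(config: ScenarioConfig, params: SimParams | None = None) -> Simulation:
    """Cell mass encapsulated in matrix; radial cue by default."""
    nx, ny, nz = config.dims
    r = config.spheroid_radius
    if 2 * r > min(config.dims):
        raise ValueError("spheroid radius exceeds half the domain")
    params = config.scaled_params(params)
    centre = (nx / 2.0, ny / 2.0, nz / 2.0)
    if config.cue in ("default", "radial"):
        cue = CueField("radial", origin=centre)
    elif config.cue == "uniform":
        cue = CueField("uniform", direction=(0.0, 0.0, 1.0))
    else:
        raise ValueError(f"unknown cue {config.cue!r}")
    sim = Simulation(config.dims, params, cue, seed=config.seed)
    # matrix everywhere, then carve the spheroid out of it
    sim.density[:] = build_texture(config.texture, config.dims)
    rng = np.random.default_rng(config.seed)
    block = (8, 8, 8)
    origins = _tile_blocks((0, nx), (0, ny), (0, nz), block)
    cb = np.asarray(centre)
    chosen = [o for o in origins
              if np.linalg.norm(np.asarray(o) + np.asarray(block) / 2.0 - cb) <= r]
    if not chosen:
        raise ValueError("spheroid radius too small to seed any cell")
    n_caf = int(round(config.caf_fraction * len(chosen))) if config.n_caf else 0
    caf_idx = set(rng.choice(len(chosen), size=n_caf, replace=False)) if n_caf else set()
    for i, origin in enumerate(chosen):
        kind = KIND_CAF if i in caf_idx else KIND_SCC
        sim.add_cell(kind, _block_voxels(origin, block))
    sim.interface = {"type": "sphere", "center": centre, "radius": float(r)}
    return sim.finalize()


def build_front_curvature_scenario(config: ScenarioConfig,
                                   params: SimParams | None = None) -> Simulation:
    """Cell slab facing matrix under a uniform cue; no fibroblasts."""
    if config.n_caf:
        raise ValueError("front-curvature scenario excludes fibroblasts")
    nx, ny, nz = config.dims
    layer = config.cell_layer_thickness
    interface_z = layer
    params = config.scaled_params(params)
    cue = CueField("uniform", direction=(0.0, 0.0, 1.0))
    sim = Simulation(config.dims, params, cue, seed=config.seed)
    tex = build_texture(config.texture, config.dims)
    sim.density[:, :, interface_z:] = tex[:, :, interface_z:]
    block = (8, 8, layer)
    for origin in _tile_blocks((0, nx), (0, ny), (0, interface_z), block):
        sim.add_cell(KIND_SCC, _block_voxels(origin, block))
    sim.interface = {"type": "plane", "z": interface_z}
    return sim.finalize()


_BUILDERS = {
    "organotypic": build_organotypic,
    "spheroid": build_spheroid,
    "front_curvature": build_front_curvature_scenario,
    "track_only": build_front_curvature_scenario,
}


def build(config: ScenarioConfig, params: SimParams | None = None) -> Simulation:
    """Dispatch to the geometry-specific builder."""
    try:
        builder = _BUILDERS[config.geometry]
    except KeyError:
        raise ValueError(f"unknown geometry {config.geometry!r}") from None
    return builder(config, params)


def config_from_dict(d: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a plain dict (YAML/JSON scenario file)."""
    d = dict(d)
    if "texture" in d and isinstance(d["texture"], dict):
        d["texture"] = TextureSpec(**d["texture"])
    if "dims" in d:
        d["dims"] = tuple(d["dims"])
    return ScenarioConfig(**d)


# Preset library: named setups at desk scale.  Counts scale with the domain,
# the physics does not.  Any field may be overridden per call.
PRESETS = {
    "organotypic_wt": dict(
        geometry="organotypic", dims=(64, 64, 72), n_caf=10),
    "organotypic_no_caf": dict(
        geometry="organotypic", dims=(64, 64, 72), n_caf=0),
    "spheroid_wt": dict(
        geometry="spheroid", dims=(64, 64, 64), n_caf=1, spheroid_radius=14),
    "spheroid_no_caf": dict(
        geometry="spheroid", dims=(64, 64, 64), n_caf=0, spheroid_radius=14),
    "front_flat": dict(
        geometry="front_curvature", dims=(64, 64, 64), n_caf=0),
    "front_single_track": dict(
        geometry="front_curvature", dims=(64, 64, 64), n_caf=0,
        texture=TextureSpec(kind="single_track", track_cross_section=(6, 6))),
    "spheroid_single_track": dict(
        geometry="spheroid", dims=(64, 64, 64), n_caf=0, spheroid_radius=14,
        texture=TextureSpec(kind="single_track", track_cross_section=(6, 6))),
}


def preset(name: str, **overrides) -> ScenarioConfig:
    try:
        defaults = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return ScenarioConfig(**{**defaults, **overrides})
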