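import dataclasses

import numpy as np
import pytest

from invasim import CueField, SimParams, Simulation
from invasim.params import KIND_CAF, KIND_MEDIUM, KIND_SCC


@pytest.fixture
def wt_params():
    return SimParams()


@pytest.fixture
def inert_params():
    """Parameters with no taxis, no barrier, no repulsion, no remodelling:
    dynamics reduce to contact + volume + surface terms (state functions)."""
    return SimParams(taxis_energy_scc=0.0, caf_taxis_override=0.0,
                     ecm_barrier=0.0, caf_repulsion_penalty=0.0,
                     ecm_entry_max_density=1.0,  # no steric exclusion
                     degradation_rate_scc=0.0, degradation_rate_caf=0.0,
                     pushing_rate_caf=0.0, pushing_rate_scc=0.0)


def make_sim(dims, params, cells, seed=0, cue=None, density=None):
    """Seed a Simulation from (kind, corner, size) cube specs."""
    cue = cue or CueField("uniform", direction=(0.0, 0.0, 1.0))
    sim = Simulation(dims, params, cue, seed=seed)
    if density is not None:
        sim.density[:] = density
    for kind, corner, size in cells:
        x, y, z = corner
        vox = np.mgrid[x:x + size, y:y + size, z:z + size].reshape(3, -1).T
        sim.add_cell(kind, vox)
    return sim.finalize()


def pair_energy_oracle(id_a, id_b, kind_of, dens_a, dens_b, params):
    """Reference contact energy between two voxels (independent of kernels)."""
    if id_a == id_b:
        return 0.0
    ka, kb = kind_of(id_a), kind_of(id_b)
    pair = {ka, kb}
    if pair == {KIND_SCC, KIND_MEDIUM}:
        rho = dens_b if kb == KIND_MEDIUM else dens_a
        return params.j_scc_ecm_zero + (params.j_scc_ecm - params.j_scc_ecm_zero) * rho
    table = {
        frozenset({KIND_SCC}): params.j_scc_scc,
        frozenset({KIND_SCC, KIND_CAF}): params.j_scc_caf,
        frozenset({KIND_CAF}): params.j_caf_caf,
        frozenset({KIND_CAF, KIND_MEDIUM}): params.j_caf_ecm,
        frozenset({KIND_MEDIUM}): 0.0,
    }
    return table[frozenset(pair)]


def full_hamiltonian(grid, density, kinds, tvol, tsurf, params):
    """Brute-force total energy: every unordered 26-neighbour pair, plus the
    volume and surface constraints of every cell.  Move-dependent terms
    (taxis, entry barrier, repulsion) are not state functions and are
    excluded; use with parameters that zero them."""
    nx, ny, nz = grid.shape

    def kind_of(cid):
        return KIND_MEDIUM if cid == 0 else int(kinds[cid])

    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) > (0, 0, 0)]  # half-space: each pair once
    contact = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = int(grid[x, y, z])
                for dx, dy, dz in offsets:
                    X, Y, Z = x + dx, y + dy, z + dz
                    if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                        b = int(grid[X, Y, Z])
                        contact += pair_energy_oracle(
                            a, b, kind_of, density[x, y, z],
                            density[X, Y, Z], params)
    constraint = 0.0
    ids = np.unique(grid[grid > 0])
    for cid in ids:
        vox = np.argwhere(grid == cid)
        vol = len(vox)
        surf = 0
        for x, y, z in vox:
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                X, Y, Z = x + dx, y + dy, z + dz
                if not (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz):
                    surf += 1
                elif grid[X, Y, Z] != cid:
                    surf += 1
        constraint += params.lambda_volume * (vol - tvol[cid]) ** 2
        constraint += params.lambda_surface * (surf - tsurf[cid]) ** 2
    return contact + constraint
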