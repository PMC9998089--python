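"""Snapshot, manifest and metric-table IO.

Snapshots are multi-page TIFFs (one page per z-slice): cell ids as 16-bit
unsigned integers (the frozen air phase is stored as 65535) and ECM density
as 32-bit float, plus a JSON run manifest with the full parameter set and
seed.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile

from . import __version__

AIR_TIFF = np.uint16(65535)


def save_snapshot(sim, out_dir: str, tag: str = "snapshot") -> dict:
    """Write cell-id and density volumes plus the run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    ids = sim.grid.astype(np.int64)
    if ids.max() >= 65535:
        raise ValueError("too many cell ids for 16-bit snapshot")
    ids16 = np.where(ids < 0, AIR_TIFF, ids).astype(np.uint16)
    # pages along z: TIFF axes (z, y, x)
    id_path = os.path.join(out_dir, f"{tag}_cells.tif")
    dens_path = os.path.join(out_dir, f"{tag}_density.tif")
    tifffile.imwrite(id_path, np.moveaxis(ids16, 2, 0))
    tifffile.imwrite(dens_path, np.moveaxis(sim.density.astype(np.float32), 2, 0))
    manifest = {
        "version": __version__,
        "dims": list(sim.dims),
        "mcs_clock": int(sim.mcs_clock),
        "seed": int(sim.seed),
        "interface": sim.interface,
        "params": sim.params.to_dict(),
        "cue": {"mode": sim.cue.mode, "direction": list(sim.cue.direction),
                "origin": list(sim.cue.origin)},
        "files": {"cells": os.path.basename(id_path),
                  "density": os.path.basename(dens_path)},
        "kinds": sim.cell_kinds()[: int(sim.next_id)].tolist(),
    }
    man_path = os.path.join(out_dir, f"{tag}_manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_snapshot(out_dir: str, tag: str = "snapshot"):
    """Read back (grid, density, kinds, interface, manifest)."""
    man_path = os.path.join(out_dir, f"{tag}_manifest.json")
    with open(man_path) as fh:
        manifest = json.load(fh)
    ids16 = tifffile.imread(os.path.join(out_dir, manifest["files"]["cells"]))
    dens = tifffile.imread(os.path.join(out_dir, manifest["files"]["density"]))
    grid = np.moveaxis(ids16.astype(np.int64), 0, 2)
    grid = np.where(grid == int(AIR_TIFF), -1, grid).astype(np.int32)
    density = np.moveaxis(dens, 0, 2).astype(np.float64)
    kinds = np.asarray(manifest["kinds"], dtype=np.int8)
    interface = manifest["interface"]
    if interface and interface.get("type") == "sphere":
        interface["center"] = tuple(interface["center"])
    return grid, density, kinds, interface, manifest
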