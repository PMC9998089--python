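"""Replicated parameter sweeps, PCA morphospace, and percentile heatmaps.

A sweep runs every combination of perturbation multipliers (cancer-cell
proteolysis, cancer-cell/cancer-cell adhesion, cancer-cell/matrix adhesion)
with a fixed number of replicates per grid point.  Per-run seeds derive
deterministically from (base seed, point index, replicate), so runs are
independent and any scheduler may execute them in any order.  Hollow or
broken-apart spheroids are flagged and excluded from PCA and heatmaps.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import metrics as _metrics
from . import scenarios
from .params import DAY4_MCS, MCS_PER_DAY

log = logging.getLogger("invasim.sweep")

PCA_METRICS = ["max_invasion", "invasion_score", "mean_neighbours",
               "tapering", "fractured_objects", "growth_rate"]


@dataclass(frozen=True)
class SweepSpec:
    """Declarative sweep: scenario preset x multiplier grid x replicates."""

    preset: str = "organotypic_wt"
    proteolysis: tuple = (1.0,)
    scc_scc_adhesion: tuple = (1.0,)
    scc_ecm_adhesion: tuple = (1.0,)
    replicates: int = 10
    base_seed: int = 0
    duration_mcs: int = DAY4_MCS
    count_interval_mcs: int = MCS_PER_DAY // 2
    overrides: dict = field(default_factory=dict)

    def points(self):
        return list(itertools.product(self.proteolysis, self.scc_scc_adhesion,
                                      self.scc_ecm_adhesion))

    def run_seed(self, point_index: int, replicate: int) -> int:
        ss = np.random.SeedSequence([self.base_seed, point_index, replicate])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def run_single(spec: SweepSpec, point_index: int, replicate: int) -> dict:
    """Run one replicate at one grid point and return its metric row."""
    prot, jcc, jcm = spec.points()[point_index]
    seed = spec.run_seed(point_index, replicate)
    config = scenarios.preset(spec.preset, proteolysis=prot,
                              scc_scc_adhesion=jcc, scc_ecm_adhesion=jcm,
                              duration_mcs=spec.duration_mcs, seed=seed,
                              **spec.overrides)
    sim = scenarios.build(config)
    times, counts = [0], [sim.scc_ids.size]
    remaining = spec.duration_mcs
    chunk = spec.count_interval_mcs
    while remaining > 0:
        step = min(chunk, remaining)
        sim.run_mcs(step)
        remaining -= step
        times.append(sim.mcs_clock)
        counts.append(sim.scc_ids.size)
    rec = _metrics.compute_record(sim, counts_times=times, counts=counts)
    row = {
        "run_id": f"p{point_index}r{replicate}",
        "scenario": spec.preset,
        "proteolysis": prot,
        "scc_scc_adhesion": jcc,
        "scc_ecm_adhesion": jcm,
        "replicate": replicate,
        "seed": seed,
    }
    row.update(rec.to_dict())
    return row


def run_sweep(spec: SweepSpec, out_dir: str | None = None,
              resume: bool = True) -> pd.DataFrame:
    """Run the full grid x replicates; returns the long-form metric table.

    With ``out_dir`` set, completed runs are check-pointed to a CSV and a
    manifest, and a resumed invocation skips them.  A failing run is logged
    and the sweep continues.
    """
    done: dict[str, dict] = {}
    csv_path = manifest_path = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        csv_path = os.path.join(out_dir, "sweep_results.csv")
        manifest_path = os.path.join(out_dir, "manifest.json")
        if resume and os.path.exists(csv_path):
            prev = pd.read_csv(csv_path)
            done = {r["run_id"]: r for r in prev.to_dict("records")}
    rows = []
    for pi in range(len(spec.points())):
        for rep in range(spec.replicates):
            run_id = f"p{pi}r{rep}"
            if run_id in done:
                rows.append(done[run_id])
                continue
            try:
                row = run_single(spec, pi, rep)
            except Exception:  # mid-run failure: log, mark, continue
                log.exception("run %s failed", run_id)
                row = {"run_id": run_id, "scenario": spec.preset,
                       "replicate": rep, "excluded": True, "failed": True}
            rows.append(row)
            if csv_path is not None:
                pd.DataFrame(rows).to_csv(csv_path, index=False)
    df = pd.DataFrame(rows)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump({"spec": dataclasses.asdict(spec), "n_rows": len(df)},
                      fh, indent=2, default=list)
    return df


def pca_morphospace(result: pd.DataFrame, metric_cols=None):
    """Z-scored PCA of the per-run metric table.

    Excluded rows are dropped; constant or all-NaN metric columns are
    dropped with a warning.  Returns a dict with scores, loading vectors,
    explained-variance fractions, and the column names used.
    """
    cols = list(metric_cols) if metric_cols is not None else list(PCA_METRICS)
    df = result
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    data = df[cols].astype(float)
    data = data.dropna(axis=0)
    keep = [c for c in cols if data[c].std() > 0]
    for c in cols:
        if c not in keep:
            log.warning("dropping constant metric column %r from PCA", c)
    if len(keep) < 2:
        raise ValueError("need at least two metric columns with variance")
    X = StandardScaler().fit_transform(data[keep].values)
    pca = PCA()
    scores = pca.fit_transform(X)
    return {
        "scores": scores,
        "loadings": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "columns": keep,
        "n_rows": X.shape[0],
    }


def heatmap_table(result: pd.DataFrame, metric: str, axes,
                  percentiles=None) -> pd.DataFrame:
    """Percentile-expanded grid for heatmap rendering.

    For each combination of the sweep axes, the metric's percentile profile
    from 0.5 to 99.5 over replicates (linear interpolation between order
    statistics), one row per grid cell.
    """
    if percentiles is None:
        percentiles = np.linspace(0.5, 99.5, 10)
    axes = list(axes)
    df = result
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    rows = []
    for key, group in df.groupby(axes):
        key = key if isinstance(key, tuple) else (key,)
        vals = group[metric].astype(float).dropna().values
        row = dict(zip(axes, key))
        for p in percentiles:
            row[f"q{p:g}"] = np.percentile(vals, p) if vals.size else np.nan
        row["n"] = vals.size
        rows.append(row)
    return pd.DataFrame(rows).sort_values(axes).reset_index(drop=True)
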