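"""Config-driven orchestration of the three study arms.

* survey arm: shoot maps (real files or synthetic cohorts) -> NN
  reconstruction -> step filter -> five-model selection, per plant and
  pooled, plus Ripley L and box-count Df per plant.
* sweep arm: factorial mu x shoot-count x threshold deposition sweep.
* experiment arm: the three shoot-mimic layouts scored for area and
  efficiency.

Every arm takes a plain dict config (YAML-loadable), an integer seed, and
an optional output directory; outputs are CSV tables with JSON sidecars
recording config, seed and version. INFO logging records every
data-reduction step (shoots merged, steps dropped) so filtering is
auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .models import DEFAULT_SMIN, fit_individuals, select_model
from .reconstruct import nearest_neighbour_route, travelling_salesman_route
from .spatial import box_count_dimension, ripley_L
from .survey import make_archetype_cohort
from .types import InvariantError, ShootMap, StepSample, pooled_sample
from .walk import WalkConfig
from .wind import (WindConfig, argmax_mu, deposition, experiment_layouts,
                   sweep, sweep_summary, LAYOUT_MU)

log = logging.getLogger("dunewalk")


def _write(df: pd.DataFrame, out_dir: Optional[Path], name: str,
           config: Mapping, seed: int) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    df.to_csv(path, index=False, float_format="%.12g")
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump({"version": dio.__version__, "seed": seed,
                   "config": dict(config)}, fh, indent=2, default=str)


def _load_maps(config: Mapping, seed: int) -> list[ShootMap]:
    """Maps from config: explicit files and/or a synthetic cohort."""
    maps: list[ShootMap] = []
    for path in config.get("shoot_maps", []):
        try:
            maps.append(dio.read_shoot_map(path, dialect=config.get("dialect")))
        except (OSError, dio.ParseError) as e:
            log.error("skipping unreadable input %s: %s", path, e)
    synth = config.get("synthetic")
    if synth:
        plants = make_archetype_cohort(
            synth.get("archetype", "arenaria_like"),
            n_plants=int(synth.get("n_plants", 8)),
            n_shoots=int(synth.get("n_shoots", 150)),
            seed=seed)
        for p in plants:
            log.info("synthetic plant %s: %d shoots (%d merged below resolution)",
                     p.map.plant_id, p.map.n_shoots, p.n_merged)
        maps.extend(p.map for p in plants)
    if not maps:
        raise InvariantError("no readable shoot maps in config")
    return maps


def run_survey(config: Mapping, seed: int = 0,
               out_dir: Optional[Path] = None) -> dict:
    """Survey arm: reconstruction, model selection and spatial statistics."""
    smin = float(config.get("smin", DEFAULT_SMIN))
    algo = config.get("algorithm", "nearest_neighbour")
    maps = _load_maps(config, seed)

    samples: list[StepSample] = []
    spatial_rows = []
    tables = []
    for smap in maps:
        if algo == "travelling_salesman":
            route, sample = travelling_salesman_route(smap, seed=seed, smin=smin)
        else:
            route, sample = nearest_neighbour_route(smap, smin=smin)
        if sample is None:
            log.warning("%s: no steps above smin, excluded", smap.plant_id)
            continue
        log.info("%s: %d shoots -> %d steps above smin=%.2f (dropped %d)",
                 smap.plant_id, smap.n_shoots, sample.n, smin,
                 smap.n_shoots - 1 - sample.n)
        samples.append(sample)
        try:
            frac = box_count_dimension(smap, fit_range=tuple(config.get("fit_range", (4.0, 16.0))))
            rip = ripley_L(smap)
            clustered = float(np.mean(rip.classification == "clustered"))
            spatial_rows.append({"plant_id": smap.plant_id, "Df": frac.Df,
                                 "r2": frac.r2, "frac_radii_clustered": clustered})
        except InvariantError as e:
            log.warning("%s: spatial stats skipped (%s)", smap.plant_id, e)

    summary = fit_individuals(samples, min_n=int(config.get("min_n", 30)))
    tables.extend(summary.tables)
    pooled = pooled_sample(samples)
    pooled_table = select_model(pooled)
    tables.append(pooled_table)
    log.info("pooled (%d steps): best model %s, truncated-Levy mu=%.3f",
             pooled.n, pooled_table.best.model,
             pooled_table["truncated_levy"].params.get("mu", float("nan")))

    sel_df = pd.concat([dio.selection_frame(t) for t in tables], ignore_index=True)
    spat_df = pd.DataFrame(spatial_rows)
    _write(sel_df, out_dir, "selection.csv", config, seed)
    _write(spat_df, out_dir, "spatial.csv", config, seed)
    return {"selection": sel_df, "spatial": spat_df, "pooled": pooled_table,
            "individuals": summary}


def _wind_config(config: Mapping) -> WindConfig:
    keys = ("incoming_speed", "deposition_fraction", "shoot_diameter", "cell",
            "a0", "Lx", "sigma_y0", "kernel_path")
    return WindConfig(**{k: config[k] for k in keys if k in config})


def run_sweep(config: Mapping, seed: int = 0,
              out_dir: Optional[Path] = None) -> dict:
    """Sweep arm: deposition area and efficiency across mu and shoot count."""
    cfg = _wind_config(config)
    walk = WalkConfig(mu=2.0, **{k: config[k] for k in ("smin", "smax") if k in config})
    table = sweep(mu_grid=config.get("mu_grid", [1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0]),
                  n_shoots_grid=config.get("n_shoots_grid", [1000]),
                  thresholds=config.get("thresholds", [cfg.deposition_fraction]),
                  n_reps=int(config.get("n_reps", 4)), seed=seed,
                  config=cfg, walk=walk)
    summary = sweep_summary(table)
    best_eff = argmax_mu(summary, "eff_mean")
    best_area = argmax_mu(summary, "area_mean")
    _write(table, out_dir, "sweep.csv", config, seed)
    _write(summary, out_dir, "sweep_summary.csv", config, seed)
    _write(best_eff, out_dir, "argmax_efficiency.csv", config, seed)
    _write(best_area, out_dir, "argmax_area.csv", config, seed)
    return {"table": table, "summary": summary,
            "argmax_efficiency": best_eff, "argmax_area": best_area}


def run_experiment(config: Mapping, seed: int = 0,
                   out_dir: Optional[Path] = None) -> pd.DataFrame:
    """Experiment arm: score the three mimic layouts over n_reps seeds."""
    cfg = _wind_config(config)
    n_shoots = int(config.get("n_shoots", 2000))
    domain = tuple(config.get("domain", (0.0, 200.0, 0.0, 200.0)))
    n_reps = int(config.get("n_reps", 3))
    rows = []
    for pattern in config.get("patterns", list(LAYOUT_MU)):
        for rep in range(n_reps):
            smap = experiment_layouts(pattern, n_shoots=n_shoots,
                                      domain=domain, seed=seed + rep)
            summ = deposition(smap, cfg, mu=LAYOUT_MU[pattern],
                              seed=seed + rep, label=pattern)
            rows.append({"pattern": pattern, "rep": rep, "seed": seed + rep,
                         "mu": summ.mu, "n_shoots": summ.n_shoots,
                         "deposition_area": summ.deposition_area,
                         "mean_step": summ.mean_step,
                         "efficiency": summ.efficiency})
            log.info("%s rep %d: area %.0f cm², efficiency %.1f cm²/cm",
                     pattern, rep, summ.deposition_area, summ.efficiency)
    df = pd.DataFrame(rows)
    _write(df, out_dir, "experiment.csv", config, seed)
    return df
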