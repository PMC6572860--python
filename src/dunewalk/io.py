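"""Readers and writers for shoot maps, step lists, wake kernels and results.

File dialects
-------------
* Shoot map: CSV with header ``shoot_id,x_cm,y_cm[,parent_id]``.
* Step list: CSV with header ``plant_id,step_cm``.
* Kernel: CSV grid of deficit fractions preceded by a 3-line ``#`` header
  carrying ``cell_cm``, ``origin_row,origin_col`` and the wind convention.
* Results: delimited table plus a JSON sidecar recording config, seed and
  package version, so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (DepositionSummary, InvariantError, KernelGrid,
                    SelectionTable, ShootMap, StepSample)

__version__ = "0.1.0"


class ParseError(ValueError):
    """Input file violates the dialect; message names the offending row."""


_DEFAULT_DIALECT = {
    "x": "x_cm",
    "y": "y_cm",
    "shoot_id": "shoot_id",
    "parent_id": "parent_id",
    "index_base": 0,
}


def read_shoot_map(path, plant_id: str | None = None,
                   dialect: Optional[Mapping] = None) -> ShootMap:
    """Read one plant's shoot coordinates (and rhizome links, if recorded).

    ``dialect`` may remap column names and set ``index_base`` (0 or 1) for
    externally produced 1-based tables.
    """
    path = Path(path)
    d = dict(_DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path)
    for col in (d["x"], d["y"]):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    try:
        xy = df[[d["x"], d["y"]]].astype(float).to_numpy()
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path.name}: non-numeric coordinate ({e})") from None
    if not np.all(np.isfinite(xy)):
        row = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise ParseError(f"{path.name}: non-finite coordinate at row {row}")

    base = int(d["index_base"])
    if d["shoot_id"] in df.columns:
        ids = df[d["shoot_id"]].astype(int).to_numpy() - base
        order = np.argsort(ids, kind="stable")
        if not np.array_equal(np.sort(ids), np.arange(len(df))):
            raise ParseError(f"{path.name}: shoot_id column is not a permutation of 0..n-1 (base {base})")
        df = df.iloc[order].reset_index(drop=True)
        xy = xy[order]
        id_of_row = {int(i): r for r, i in enumerate(ids[order])}
    else:
        id_of_row = {i: i for i in range(len(df))}

    parent = None
    if d["parent_id"] in df.columns:
        raw = df[d["parent_id"]]
        parent = np.full(len(df), -1, dtype=int)
        for row, v in enumerate(raw):
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                continue
            pid = int(v) - base
            if pid not in id_of_row:
                raise ParseError(f"{path.name}: row {row} references unknown parent_id {v}")
            parent[row] = id_of_row[pid]
    try:
        return ShootMap(plant_id=plant_id or path.stem, xy=xy, parent_index=parent)
    except InvariantError as e:
        raise ParseError(f"{path.name}: {e}") from None


def write_shoot_map(smap: ShootMap, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "shoot_id": np.arange(smap.n_shoots),
        "x_cm": smap.xy[:, 0],
        "y_cm": smap.xy[:, 1],
    })
    if smap.parent_index is not None:
        df["parent_id"] = [("" if p < 0 else p) for p in smap.parent_index]
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_step_list(path, smin: float, provenance: str = "excavated") -> list[StepSample]:
    """Read a ``plant_id,step_cm`` table into per-plant samples, filtering at smin."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("plant_id", "step_cm"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    out = []
    for pid, grp in df.groupby("plant_id", sort=False):
        steps = grp["step_cm"].astype(float).to_numpy()
        steps = steps[steps >= smin]
        if steps.size:
            out.append(StepSample(steps=steps, smin=smin, provenance=provenance, plant_id=str(pid)))
    return out


def write_step_list(samples: Iterable[StepSample], path) -> Path:
    path = Path(path)
    rows = [(s.plant_id, v) for s in samples for v in s.steps]
    pd.DataFrame(rows, columns=["plant_id", "step_cm"]).to_csv(
        path, index=False, float_format="%.12g")
    return path


def read_kernel(path) -> KernelGrid:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for _ in range(3):
            line = fh.readline()
            if not line.startswith("#"):
                raise ParseError(f"{path.name}: expected 3 '#' header lines")
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    try:
        cell = float(meta["cell_cm"])
        r0, c0 = (int(v) for v in meta["origin"].split(","))
    except (KeyError, ValueError) as e:
        raise ParseError(f"{path.name}: bad kernel header ({e})") from None
    if meta.get("wind", "+x") != "+x":
        raise ParseError(f"{path.name}: unsupported wind convention {meta.get('wind')!r}")
    return KernelGrid(values=values, cell=cell, origin=(r0, c0))


def write_kernel(kernel: KernelGrid, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cell_cm = {kernel.cell:.12g}\n")
        fh.write(f"# origin = {kernel.origin[0]},{kernel.origin[1]}\n")
        fh.write("# wind = +x\n")
        np.savetxt(fh, kernel.values, delimiter=",", fmt="%.12g")
    return path


def selection_frame(table: SelectionTable) -> pd.DataFrame:
    rows = []
    for f in table.fits:
        rows.append({
            "sample_id": table.sample_id,
            "model": f.model,
            "params": json.dumps({k: (None if v is None else float(v)) for k, v in f.params.items()}),
            "loglik": f.loglik, "k": f.k, "aic": f.aic, "waic": f.waic,
            "ks_stat": f.ks_stat, "ks_p": f.ks_p,
            "degenerate": f.degenerate, "reason": f.reason,
        })
    return pd.DataFrame(rows)


def frame_to_selection(df: pd.DataFrame) -> SelectionTable:
    from .types import FitResult
    fits = []
    for _, r in df.iterrows():
        fits.append(FitResult(
            model=r["model"], params=json.loads(r["params"]),
            loglik=float(r["loglik"]), k=int(r["k"]), aic=float(r["aic"]),
            waic=float(r["waic"]), ks_stat=float(r["ks_stat"]), ks_p=float(r["ks_p"]),
            degenerate=bool(r["degenerate"]), reason=str(r["reason"]) if pd.notna(r["reason"]) else "",
        ))
    return SelectionTable(sample_id=str(df["sample_id"].iloc[0]) if len(df) else "", fits=fits)


def write_results(obj, path, config: Optional[Mapping] = None,
                  seed: Optional[int] = None) -> Path:
    """Write a SelectionTable (or list of them) or DepositionSummary list.

    Emits ``<path>`` as CSV plus ``<path>.meta.json`` recording config, seed
    and version; the pair round-trips losslessly at 12 significant digits.
    """
    path = Path(path)
    if isinstance(obj, SelectionTable):
        df = selection_frame(obj)
        kind = "selection"
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], SelectionTable):
        df = pd.concat([selection_frame(t) for t in obj], ignore_index=True)
        kind = "selection"
    elif isinstance(obj, (list, tuple)) and (not obj or isinstance(obj[0], DepositionSummary)):
        df = pd.DataFrame([asdict(s) for s in obj],
                          columns=["label", "mu", "n_shoots", "deposition_area",
                                   "mean_step", "efficiency", "threshold", "seed"])
        kind = "deposition"
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {"kind": kind, "version": __version__, "seed": seed,
               "config": dict(config) if config else {}}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
    return path


def read_results(path):
    """Inverse of :func:`write_results`; returns (object, sidecar dict)."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".meta.json")) as fh:
        sidecar = json.load(fh)
    df = pd.read_csv(path)
    if sidecar["kind"] == "selection":
        tables = [frame_to_selection(g) for _, g in df.groupby("sample_id", sort=False)]
        obj = tables[0] if len(tables) == 1 else tables
    else:
        obj = [DepositionSummary(
            mu=float(r["mu"]), n_shoots=int(r["n_shoots"]),
            deposition_area=float(r["deposition_area"]), mean_step=float(r["mean_step"]),
            efficiency=float(r["efficiency"]),
            seed=None if pd.isna(r["seed"]) else int(r["seed"]),
            threshold=float(r["threshold"]), label=str(r["label"]) if pd.notna(r["label"]) else "",
        ) for _, r in df.iterrows()]
    return obj, sidecar
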