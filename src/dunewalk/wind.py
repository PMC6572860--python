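"""Gridded wind-attenuation model scoring sand capture of shoot patterns.

Each shoot sheds a downwind wake of reduced wind speed; the wakes of all
shoots superpose additively (clamped so the wind cannot reverse). Where the
local speed falls below a fixed fraction of the free-stream speed, airborne
sand is assumed to deposit. A configuration's raw score is the total
deposition area; its cost-normalized score divides that area by the mean
rhizome length invested per shoot (sand-trapping efficiency, cm² of
deposition per cm of rhizome).

The single-shoot wake is a parametric analytic kernel — exponential decay
downwind, Gaussian spread crosswind, widening like a turbulent wake — with
a file-load escape hatch for kernels produced elsewhere. Default kernel
parameters come from the shipped calibration script
(``scripts/calibrate_kernel.py``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .types import (DepositionSummary, InvariantError, KernelGrid, ShootMap)
from .walk import WalkConfig, simulate_walk

#: calibrated analytic-wake defaults (see scripts/calibrate_kernel.py)
DEFAULT_A0 = 0.65        # peak fractional velocity deficit at the shoot
DEFAULT_LX = 12.0        # downstream e-folding length, cm
DEFAULT_SIGMA_Y0 = 1.2   # crosswind Gaussian scale at the shoot, cm
KERNEL_FLOOR = 0.005     # deficits below this are truncated to zero


@dataclass
class WindConfig:
    incoming_speed: float = 6.5          # m/s, free stream
    deposition_fraction: float = 0.61    # deposit where u/u0 < this
    shoot_diameter: float = 1.5          # mm
    cell: float = 0.5                    # cm, grid resolution
    a0: float = DEFAULT_A0
    Lx: float = DEFAULT_LX
    sigma_y0: float = DEFAULT_SIGMA_Y0
    kernel_path: Optional[str] = None    # load a kernel file instead

    def __post_init__(self) -> None:
        if not (0.0 < self.deposition_fraction < 1.0):
            raise InvariantError("deposition_fraction must lie in (0, 1)")
        if self.cell <= 0:
            raise InvariantError("cell size must be positive")
        if not (0.0 < self.a0 < 1.0):
            raise InvariantError("peak deficit a0 must lie in (0, 1)")
        if self.Lx <= 0 or self.sigma_y0 <= 0:
            raise InvariantError("Lx and sigma_y0 must be positive")


@dataclass
class WindField:
    """Fractional wind speed u/u0 on a regular grid covering the pattern."""

    u: np.ndarray        # (rows, cols), u/u0 in [0, 1]
    cell: float
    x0: float            # world x of cell column 0 (cell centre), cm
    y0: float            # world y of cell row 0, cm

    def deposition_area(self, fraction: float) -> float:
        return float(np.count_nonzero(self.u < fraction)) * self.cell ** 2


def analytic_kernel(config: WindConfig) -> KernelGrid:
    """Single-shoot wake kernel on the model grid.

    deficit(x, y) = a0 · exp(−x/Lx) · exp(−y² / (2 σy(x)²)) for x ≥ 0
    downwind, with σy(x) = σy0·√(1 + x/Lx); upwind of the shoot the deficit
    persists only within one shoot diameter (the stagnation zone) and is
    zero beyond. The grid is truncated where the deficit falls below
    ``KERNEL_FLOOR``.
    """
    a0, Lx, sy0, cell = config.a0, config.Lx, config.sigma_y0, config.cell
    x_max = Lx * math.log(a0 / KERNEL_FLOOR)
    diam_cm = config.shoot_diameter / 10.0
    n_down = int(math.ceil(x_max / cell))
    n_up = int(math.ceil(diam_cm / cell))
    xs = np.arange(-n_up, n_down + 1) * cell
    sy_far = sy0 * math.sqrt(1.0 + x_max / Lx)
    y_max = sy_far * math.sqrt(2.0 * math.log(a0 / KERNEL_FLOOR))
    n_y = int(math.ceil(y_max / cell))
    ys = np.arange(-n_y, n_y + 1) * cell

    X, Y = np.meshgrid(xs, ys)  # rows = y, cols = x
    Xe = np.maximum(X, 0.0)     # stagnation zone uses the x=0 profile
    sy = sy0 * np.sqrt(1.0 + Xe / Lx)
    deficit = a0 * np.exp(-Xe / Lx) * np.exp(-(Y ** 2) / (2.0 * sy ** 2))
    deficit[X < -diam_cm] = 0.0
    deficit[deficit < KERNEL_FLOOR] = 0.0
    return KernelGrid(values=deficit, cell=cell, origin=(n_y, n_up))


def load_kernel(config: WindConfig) -> KernelGrid:
    if config.kernel_path is not None:
        from .io import read_kernel
        kern = read_kernel(config.kernel_path)
        if abs(kern.cell - config.cell) > 1e-9:
            raise InvariantError(
                f"kernel cell {kern.cell} cm does not match config cell {config.cell} cm")
        return kern
    return analytic_kernel(config)


def wind_field(smap: ShootMap, config: WindConfig,
               kernel: Optional[KernelGrid] = None) -> WindField:
    """Convolve the shoot grid with the single-shoot wake kernel.

    The domain is the shoot bounding box padded by the kernel extent, so no
    wake is clipped (an effectively infinite domain). Deficits add per
    shoot, are clamped to [0, 1], and u/u0 = 1 − deficit.
    """
    if smap.n_shoots < 1:
        raise InvariantError("empty shoot map")
    kern = kernel if kernel is not None else load_kernel(config)
    cell = config.cell
    K = kern.values
    kr, kc = K.shape
    orr, orc = kern.origin
    pad_left, pad_right = orc, kc - 1 - orc
    pad_bot, pad_top = orr, kr - 1 - orr

    xmin, ymin = smap.xy.min(axis=0)
    xmax, ymax = smap.xy.max(axis=0)
    # grid of cell centres; shoots rasterized by nearest cell centre
    x0 = xmin - pad_left * cell
    y0 = ymin - pad_bot * cell
    ncols = int(round((xmax - xmin) / cell)) + 1 + pad_left + pad_right
    nrows = int(round((ymax - ymin) / cell)) + 1 + pad_bot + pad_top
    counts = np.zeros((nrows, ncols))
    cols = np.rint((smap.xy[:, 0] - x0) / cell).astype(int)
    rows = np.rint((smap.xy[:, 1] - y0) / cell).astype(int)
    np.add.at(counts, (rows, cols), 1.0)

    full = fftconvolve(counts, K, mode="full")
    deficit = full[orr:orr + nrows, orc:orc + ncols]
    deficit = np.clip(deficit, 0.0, 1.0)
    return WindField(u=1.0 - deficit, cell=cell, x0=x0, y0=y0)


def brute_force_field(smap: ShootMap, config: WindConfig,
                      kernel: Optional[KernelGrid] = None) -> WindField:
    """Per-shoot deficit summation without the convolution shortcut.

    Same grid and result as :func:`wind_field`; kept as the independent
    reference for small maps.
    """
    kern = kernel if kernel is not None else load_kernel(config)
    ref = wind_field(smap, config, kern)  # reuse grid geometry
    nrows, ncols = ref.u.shape
    cell = config.cell
    K = kern.values
    kr, kc = K.shape
    orr, orc = kern.origin
    deficit = np.zeros((nrows, ncols))
    for x, y in smap.xy:
        c = int(round((x - ref.x0) / cell))
        r = int(round((y - ref.y0) / cell))
        r_lo, r_hi = r - orr, r - orr + kr
        c_lo, c_hi = c - orc, c - orc + kc
        rs_lo, rs_hi = max(r_lo, 0), min(r_hi, nrows)
        cs_lo, cs_hi = max(c_lo, 0), min(c_hi, ncols)
        deficit[rs_lo:rs_hi, cs_lo:cs_hi] += K[rs_lo - r_lo:kr - (r_hi - rs_hi),
                                               cs_lo - c_lo:kc - (c_hi - cs_hi)]
    deficit = np.clip(deficit, 0.0, 1.0)
    return WindField(u=1.0 - deficit, cell=cell, x0=ref.x0, y0=ref.y0)


def mean_rhizome_length(smap: ShootMap) -> float:
    """Mean inter-shoot rhizome investment, cm.

    Uses ground-truth parent links when recorded; otherwise the NN route.
    All links count, including those below the 0.68 cm analysis cutoff —
    investment is physical, not observational. NaN for a single shoot.
    """
    if smap.n_shoots < 2:
        return float("nan")
    if smap.parent_index is not None:
        return float(smap.rhizome_lengths().mean())
    from .reconstruct import nearest_neighbour_route
    route, _ = nearest_neighbour_route(smap)
    d = np.hypot(*(smap.xy[route.order[1:]] - smap.xy[route.order[:-1]]).T)
    return float(d.mean())


def deposition(smap: ShootMap, config: WindConfig,
               kernel: Optional[KernelGrid] = None,
               field_: Optional[WindField] = None,
               mu: float = float("nan"), seed: Optional[int] = None,
               label: str = "") -> DepositionSummary:
    """Score one configuration: deposition area and trapping efficiency."""
    fld = field_ if field_ is not None else wind_field(smap, config, kernel)
    area = fld.deposition_area(config.deposition_fraction)
    mean_step = mean_rhizome_length(smap)
    eff = area / mean_step if mean_step and not math.isnan(mean_step) else float("nan")
    return DepositionSummary(mu=mu, n_shoots=smap.n_shoots, deposition_area=area,
                             mean_step=mean_step, efficiency=eff, seed=seed,
                             threshold=config.deposition_fraction, label=label)


def sweep(mu_grid: Sequence[float], n_shoots_grid: Sequence[int],
          thresholds: Sequence[float] = (0.61,), n_reps: int = 4,
          seed: int = 0, config: Optional[WindConfig] = None,
          walk: Optional[WalkConfig] = None) -> pd.DataFrame:
    """Full-factorial deposition sweep over mu x shoot count x threshold.

    Each (mu, n_shoots, rep) resamples a fresh walk (seeds recorded); the
    wind field is computed once per walk and re-thresholded per threshold.
    Returns the long-format table of DepositionSummary rows.
    """
    cfg = config or WindConfig()
    base_walk = walk or WalkConfig()
    kern = load_kernel(cfg)
    ss = np.random.SeedSequence(seed)
    rows = []
    for mu in mu_grid:
        for n_shoots in n_shoots_grid:
            for rep in range(n_reps):
                wseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                wcfg = replace(base_walk, mu=float(mu), n_shoots=int(n_shoots), seed=wseed)
                smap = simulate_walk(wcfg)
                fld = wind_field(smap, cfg, kern)
                mean_step = mean_rhizome_length(smap)
                for thr in thresholds:
                    area = fld.deposition_area(thr)
                    eff = area / mean_step if mean_step else float("nan")
                    rows.append({"mu": float(mu), "n_shoots": int(n_shoots),
                                 "threshold": float(thr), "rep": rep, "seed": wseed,
                                 "deposition_area": area, "mean_step": mean_step,
                                 "efficiency": eff})
    return pd.DataFrame(rows)


def sweep_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean ± s.e.m. per (mu, n_shoots, threshold) condition."""
    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    g = table.groupby(["mu", "n_shoots", "threshold"], as_index=False)
    out = g.agg(area_mean=("deposition_area", "mean"), area_sem=("deposition_area", sem),
                eff_mean=("efficiency", "mean"), eff_sem=("efficiency", sem),
                mean_step=("mean_step", "mean"))
    return out


def argmax_mu(summary: pd.DataFrame, metric: str = "eff_mean") -> pd.DataFrame:
    """Per (n_shoots, threshold) condition, the mu maximizing ``metric``."""
    rows = []
    for (n_shoots, thr), grp in summary.groupby(["n_shoots", "threshold"]):
        best = grp.loc[grp[metric].idxmax()]
        rows.append({"n_shoots": n_shoots, "threshold": thr,
                     "best_mu": float(best["mu"]), metric: float(best[metric])})
    return pd.DataFrame(rows)


LAYOUT_MU = {"dispersed": 1.1, "patchy": 2.0, "single_patch": 3.0}


def experiment_layouts(pattern: str, n_shoots: int = 2000,
                       domain: tuple[float, float, float, float] = (0.0, 200.0, 0.0, 200.0),
                       seed: int = 0) -> ShootMap:
    """Shoot-mimic layouts emulating the field experiment's three plantings.

    'dispersed' (ballistic-like, mu 1.1), 'patchy' (Levy-like, mu 2.0) and
    'single_patch' (Brownian-like, mu 3.0) walks confined to the plot
    domain (default 2 m x 2 m, ~500 shoots per m²).
    """
    if pattern not in LAYOUT_MU:
        raise InvariantError(f"unknown layout {pattern!r}; choose from {sorted(LAYOUT_MU)}")
    xmin, xmax, ymin, ymax = domain
    area_m2 = (xmax - xmin) * (ymax - ymin) / 1e4
    density = n_shoots / area_m2
    if density > 2000.0:
        raise InvariantError(f"density {density:.0f} shoots/m² infeasible for the plot")
    cfg = WalkConfig(mu=LAYOUT_MU[pattern], n_shoots=n_shoots, seed=seed)
    centre = ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
    smap = simulate_walk(cfg, domain=domain, origin=centre)
    smap.plant_id = f"{pattern}-seed{seed}"
    smap.species_label = pattern
    return smap
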