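"""Survey-like synthetic plants with known ground truth.

Field maps of real plants carry two artefacts a raw simulated walk lacks:
positional jitter at the ~0.34 cm digitization error, and pairs of pins too
close to resolve (< 0.68 cm) collapsing into one. This module applies both
to simulated walks so every downstream stage — reconstruction, fitting,
spatial statistics — can be exercised against known ground truth without
the deposited field data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .distributions import sample_mixture
from .types import InvariantError, ShootMap, MIN_STEP_CM, RESOLUTION_CM
from .walk import WalkConfig, simulate_walk, DEFAULT_SMIN

#: Two-mode exponential mixture (w1, lam1, lam2; rates in 1/cm above smin)
#: emulating the breviligulata-like archetype: a composite Brownian walker
#: whose truncated-Levy fit lands near mu = 1.5. Values frozen by
#: scripts/calibrate_mixture.py.
BREVILIGULATA_MIX = (0.6, 1.5, 0.08)

#: Pooled Levy exponent of the arenaria-like archetype.
ARENARIA_MU = 1.98


@dataclass
class SurveyPlant:
    """A survey-processed plant plus its generating ground truth."""

    map: ShootMap               # jittered + merged; parent links kept current
    truth: ShootMap             # the raw simulated walk
    true_mu: Optional[float]    # generating exponent (None for mixtures)
    n_merged: int               # shoots lost to sub-resolution merging
    config: Optional[WalkConfig] = None


def merge_unresolvable(smap: ShootMap, merge_below: float) -> tuple[ShootMap, int]:
    """Collapse shoot pairs closer than ``merge_below`` to their midpoint.

    Pairs are merged closest-first, repeatedly, until no pair is below the
    cutoff (emulating pins that read as a single shoot). Parent links are
    remapped onto the surviving shoot.
    """
    xy = smap.xy.copy()
    parent = None if smap.parent_index is None else smap.parent_index.copy()
    n_merged = 0
    while xy.shape[0] > 1:
        D = squareform(pdist(xy))
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] >= merge_below:
            break
        i, j = min(i, j), max(i, j)
        xy[i] = (xy[i] + xy[j]) / 2.0
        keep = np.arange(xy.shape[0]) != j
        if parent is not None:
            # children of j adopt the surviving shoot i (i < j, so the
            # "parent precedes child" invariant is preserved by the shift)
            parent = np.where(parent == j, i, parent)
            parent = parent[keep]
            parent = np.where(parent > j, parent - 1, parent)
        xy = xy[keep]
        n_merged += 1
    out = ShootMap(plant_id=smap.plant_id, xy=xy, parent_index=parent,
                   species_label=smap.species_label, resolution=smap.resolution)
    return out, n_merged


def make_survey_plant(config: WalkConfig, jitter: float = RESOLUTION_CM,
                      merge_below: float = MIN_STEP_CM,
                      seed: Optional[int] = None) -> SurveyPlant:
    """Simulate a walk and degrade it the way the survey protocol would.

    Isotropic Gaussian jitter of scale ``jitter`` is added to every shoot,
    then unresolvable pairs (< ``merge_below`` apart) are merged. With both
    set to zero the output is the raw walk.
    """
    if jitter < 0 or merge_below < 0:
        raise InvariantError("jitter and merge_below must be non-negative")
    truth = simulate_walk(config)
    xy = truth.xy
    if jitter > 0:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
        xy = xy + rng.normal(0.0, jitter, size=xy.shape)
    degraded = ShootMap(plant_id=truth.plant_id, xy=xy,
                        parent_index=None if truth.parent_index is None
                        else truth.parent_index.copy(),
                        species_label=truth.species_label, resolution=RESOLUTION_CM)
    if merge_below > 0:
        degraded, n_merged = merge_unresolvable(degraded, merge_below)
    else:
        n_merged = 0
    return SurveyPlant(map=degraded, truth=truth, true_mu=config.mu,
                       n_merged=n_merged, config=config)


def chain_from_steps(steps: np.ndarray, seed: int,
                     plant_id: str = "chain") -> ShootMap:
    """Non-branching uniform-angle walk realizing a given step-length list."""
    steps = np.asarray(steps, dtype=float)
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=steps.size)
    dxy = np.column_stack([steps * np.cos(angles), steps * np.sin(angles)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])
    parent = np.arange(-1, steps.size)
    return ShootMap(plant_id=plant_id, xy=xy, parent_index=parent)


ARCHETYPES = ("arenaria_like", "breviligulata_like")


def make_archetype_cohort(archetype: str, n_plants: int, seed: int = 0,
                          n_shoots: int = 150,
                          jitter: float = RESOLUTION_CM,
                          merge_below: float = MIN_STEP_CM) -> list[SurveyPlant]:
    """Cohort of survey plants drawn from one strategy archetype.

    arenaria_like: truncated-Pareto steps at the pooled exponent mu = 1.98.
    breviligulata_like: two-mode exponential (composite Brownian) steps with
    the calibrated mixture constants; its truncated-Levy fit lands near 1.5.
    """
    if archetype not in ARCHETYPES:
        raise InvariantError(f"unknown archetype {archetype!r}")
    if n_plants < 1:
        raise InvariantError("n_plants must be >= 1")
    ss = np.random.SeedSequence(seed)
    plants = []
    for p in range(n_plants):
        pseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        if archetype == "arenaria_like":
            cfg = WalkConfig(mu=ARENARIA_MU, n_shoots=n_shoots, seed=pseed)
            plant = make_survey_plant(cfg, jitter=jitter, merge_below=merge_below,
                                      seed=pseed + 1)
            plant.map.species_label = archetype
        else:
            rng = np.random.default_rng(pseed)
            w1, lam1, lam2 = BREVILIGULATA_MIX
            steps = sample_mixture(rng, n_shoots - 1, w1, lam1, lam2, DEFAULT_SMIN)
            truth = chain_from_steps(steps, seed=pseed + 1,
                                     plant_id=f"{archetype}-{p}")
            xy = truth.xy
            if jitter > 0:
                xy = xy + rng.normal(0.0, jitter, size=xy.shape)
            degraded = ShootMap(plant_id=truth.plant_id, xy=xy,
                                parent_index=truth.parent_index.copy(),
                                species_label=archetype)
            n_merged = 0
            if merge_below > 0:
                degraded, n_merged = merge_unresolvable(degraded, merge_below)
            plant = SurveyPlant(map=degraded, truth=truth, true_mu=None,
                                n_merged=n_merged, config=None)
        plants.append(plant)
    return plants
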