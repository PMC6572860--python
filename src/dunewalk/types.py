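"""Shared domain containers.

All coordinates are continuous 2D Cartesian centimetres in a plant-local
frame (y up); wind, where it matters, blows along +x. Shoot arrays are
0-based internally; files carry explicit ``shoot_id`` so 1-based external
data import cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Positional measurement error of the pin-mapping protocol (cm).
RESOLUTION_CM = 0.34
#: Minimum resolvable inter-shoot distance: twice the positional error (cm).
MIN_STEP_CM = 0.68

VALID_PROVENANCES = ("excavated", "nearest_neighbour", "travelling_salesman", "simulated")
MODEL_NAMES = ("brownian", "levy", "truncated_levy", "composite_brownian", "lognormal")


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass
class ShootMap:
    """Per-plant shoot coordinates with optional rhizome topology.

    ``parent_index[i]`` is the index of the shoot that shoot ``i`` grew from
    (-1 for the root); when present it must reference an earlier-listed shoot,
    which makes the topology acyclic by construction.
    """

    plant_id: str
    xy: np.ndarray  # (n, 2) float, cm
    species_label: str = ""
    parent_index: Optional[np.ndarray] = None  # (n,) int, -1 = root
    resolution: float = RESOLUTION_CM

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise InvariantError(f"{self.plant_id}: coordinates must be (n, 2), got {self.xy.shape}")
        if self.xy.shape[0] < 1:
            raise InvariantError(f"{self.plant_id}: a shoot map needs at least one shoot")
        if not np.all(np.isfinite(self.xy)):
            bad = int(np.flatnonzero(~np.isfinite(self.xy).all(axis=1))[0])
            raise InvariantError(f"{self.plant_id}: non-finite coordinate at shoot {bad}")
        if self.parent_index is not None:
            self.parent_index = np.asarray(self.parent_index, dtype=int)
            if self.parent_index.shape != (self.n_shoots,):
                raise InvariantError(f"{self.plant_id}: parent_index length mismatch")
            idx = np.arange(self.n_shoots)
            bad = np.flatnonzero((self.parent_index >= idx) & (self.parent_index != -1))
            if bad.size:
                i = int(bad[0])
                raise InvariantError(
                    f"{self.plant_id}: shoot {i} has parent {int(self.parent_index[i])}; "
                    "parents must be earlier-listed shoots (cycles are impossible only then)"
                )
            if self.parent_index.min() < -1:
                raise InvariantError(f"{self.plant_id}: parent index below -1")

    @property
    def n_shoots(self) -> int:
        return int(self.xy.shape[0])

    def rhizome_lengths(self) -> np.ndarray:
        """Euclidean lengths of all parent->child links (requires topology)."""
        if self.parent_index is None:
            raise InvariantError(f"{self.plant_id}: no rhizome topology recorded")
        child = np.flatnonzero(self.parent_index >= 0)
        parent = self.parent_index[child]
        return np.hypot(*(self.xy[child] - self.xy[parent]).T)

    def true_links(self) -> set[tuple[int, int]]:
        """Undirected parent-child pairs, as sorted index tuples."""
        if self.parent_index is None:
            raise InvariantError(f"{self.plant_id}: no rhizome topology recorded")
        out = set()
        for i, p in enumerate(self.parent_index):
            if p >= 0:
                out.add((min(i, int(p)), max(i, int(p))))
        return out


@dataclass
class StepSample:
    """Filtered list of inter-shoot step lengths with provenance."""

    steps: np.ndarray
    smin: float
    provenance: str = "simulated"
    plant_id: str = ""

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float).ravel()
        if self.provenance not in VALID_PROVENANCES:
            raise InvariantError(f"unknown provenance {self.provenance!r}")
        if self.n < 1:
            raise InvariantError("a step sample needs at least one step")
        if not (self.smin > 0):
            raise InvariantError("smin must be positive")
        if self.steps.min() < self.smin:
            raise InvariantError(
                f"step {self.steps.min():g} cm below smin={self.smin:g} cm; filter before constructing"
            )

    @property
    def n(self) -> int:
        return int(self.steps.size)

    @property
    def smax(self) -> float:
        return float(self.steps.max())


@dataclass
class FitResult:
    """One candidate model's maximum-likelihood fit."""

    model: str
    params: dict
    loglik: float
    k: int
    aic: float = np.nan
    waic: float = np.nan
    ks_stat: float = np.nan
    ks_p: float = np.nan
    degenerate: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise InvariantError(f"unknown model {self.model!r}")
        if np.isnan(self.aic) and not self.degenerate:
            self.aic = 2.0 * self.k - 2.0 * self.loglik


@dataclass
class SelectionTable:
    """All candidate fits for one sample, with Akaike weights attached."""

    sample_id: str
    fits: list[FitResult] = field(default_factory=list)

    @property
    def valid_fits(self) -> list[FitResult]:
        return [f for f in self.fits if not f.degenerate]

    @property
    def best(self) -> FitResult:
        return max(self.valid_fits, key=lambda f: f.waic)

    def __getitem__(self, model: str) -> FitResult:
        for f in self.fits:
            if f.model == model:
                return f
        raise KeyError(model)


@dataclass
class KernelGrid:
    """Single-shoot fractional wind-velocity deficit on a regular grid.

    ``values[r, c]`` is the deficit (0..1) at cell (r, c); the shoot sits at
    ``origin``; columns increase downwind (+x), rows increase with +y.
    """

    values: np.ndarray
    cell: float
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvariantError("kernel must be a 2D grid")
        if self.cell <= 0:
            raise InvariantError("cell size must be positive")
        if self.values.min() < 0 or self.values.max() > 1:
            raise InvariantError("kernel deficits must lie in [0, 1]")
        r0, c0 = self.origin
        if not (0 <= r0 < self.values.shape[0] and 0 <= c0 < self.values.shape[1]):
            raise InvariantError("kernel origin outside the grid")


@dataclass
class DepositionSummary:
    """Sand-capture score of one shoot configuration."""

    mu: float
    n_shoots: int
    deposition_area: float  # cm^2
    mean_step: float  # cm; nan when undefined (single shoot / no links)
    efficiency: float  # cm^2 / cm; nan when mean_step undefined
    seed: Optional[int] = None
    threshold: float = np.nan
    label: str = ""


def pooled_sample(samples: Sequence[StepSample], provenance: str | None = None) -> StepSample:
    """Concatenate per-plant step samples into one pooled sample."""
    if not samples:
        raise InvariantError("nothing to pool")
    smin = max(s.smin for s in samples)
    steps = np.concatenate([s.steps for s in samples])
    steps = steps[steps >= smin]
    return StepSample(steps=steps, smin=smin,
                      provenance=provenance or samples[0].provenance,
                      plant_id="pooled")
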