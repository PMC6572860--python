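"""Rhizome-network reconstruction from shoot coordinates alone.

Excavating a rhizome network is destructive and slow; these two connecting
algorithms estimate the step-size distribution straight from the mapped
shoot positions. The nearest-neighbour (NN) chain is the default in the
pipeline — it is the simplest and carries the fewest assumptions — and the
open-path travelling-salesman (TS) route is the more expensive alternative.
Either route's consecutive distances, filtered at the resolvability cutoff,
form the estimated step sample; a two-sample KS test against excavated
(ground-truth) steps validates the reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .types import InvariantError, ShootMap, StepSample, MIN_STEP_CM


@dataclass
class Route:
    order: np.ndarray          # visiting order of shoot indices
    total_length: float

    def links(self) -> set[tuple[int, int]]:
        o = self.order
        return {(min(a, b), max(a, b)) for a, b in zip(o[:-1], o[1:])}


def _route_length(order: np.ndarray, D: np.ndarray) -> float:
    return float(D[order[:-1], order[1:]].sum())


def _greedy_chain(start: int, D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    order = np.empty(n, dtype=int)
    order[0] = start
    remaining = np.ones(n, dtype=bool)
    remaining[start] = False
    cur = start
    for k in range(1, n):
        row = np.where(remaining, D[cur], np.inf)
        cur = int(np.argmin(row))  # argmin takes the lowest index on ties
        order[k] = cur
        remaining[cur] = False
    return order


def nearest_neighbour_route(smap: ShootMap, smin: float = MIN_STEP_CM
                            ) -> tuple[Route, StepSample | None]:
    """Best-of-N greedy nearest-neighbour chain.

    A greedy chain is grown from every possible starting shoot; the chain of
    minimum total Euclidean length wins (lowest-index start on exact ties).
    The returned StepSample holds the consecutive route distances at or
    above ``smin``; sub-cutoff pins still anchor the route, they are only
    dropped from the sample afterwards.
    """
    if smap.n_shoots < 2:
        warnings.warn("single shoot: empty step sample", stacklevel=2)
        return Route(order=np.array([0]), total_length=0.0), None
    D = squareform(pdist(smap.xy))
    best_order, best_len = None, np.inf
    for start in range(smap.n_shoots):
        order = _greedy_chain(start, D)
        length = _route_length(order, D)
        if length < best_len:
            best_order, best_len = order, length
    route = Route(order=best_order, total_length=best_len)
    return route, route_steps(route, smap, smin, "nearest_neighbour")


def route_steps(route: Route, smap: ShootMap, smin: float,
                provenance: str) -> StepSample | None:
    d = np.hypot(*(smap.xy[route.order[1:]] - smap.xy[route.order[:-1]]).T)
    d = d[d >= smin]
    if d.size == 0:
        warnings.warn("all route steps below smin", stacklevel=2)
        return None
    return StepSample(steps=d, smin=smin, provenance=provenance, plant_id=smap.plant_id)


def _two_opt(order: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, float]:
    """2-opt local search on an open path (segment reversals, incl. prefixes)."""
    order = order.copy()
    n = order.size
    improved = True
    while improved:
        improved = False
        for i in range(0, n - 1):
            o_i = order[i]
            d_prev = D[order[i - 1], o_i] if i > 0 else 0.0
            # reversing order[i..j]: replaces edges (i-1,i) and (j,j+1)
            js = np.arange(i + 1, n)
            o_j = order[js]
            d_next = np.where(js < n - 1, D[o_j, order[np.minimum(js + 1, n - 1)]], 0.0)
            new_prev = D[order[i - 1], o_j] if i > 0 else 0.0
            new_next = np.where(js < n - 1, D[o_i, order[np.minimum(js + 1, n - 1)]], 0.0)
            delta = (new_prev + new_next) - (d_prev + d_next)
            kbest = int(np.argmin(delta))
            if delta[kbest] < -1e-12:
                j = int(js[kbest])
                order[i:j + 1] = order[i:j + 1][::-1]
                improved = True
    return order, _route_length(order, D)


def _double_bridge(order: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = order.size
    if n < 5:
        cuts = sorted(rng.choice(np.arange(1, n), size=min(2, n - 1), replace=False))
        parts = np.split(order, cuts)
        idx = rng.permutation(len(parts))
        return np.concatenate([parts[i] for i in idx])
    cuts = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
    a, b, c = cuts
    return np.concatenate([order[:a], order[b:c], order[a:b], order[c:]])


def travelling_salesman_route(smap: ShootMap, seed: int = 0,
                              smin: float = MIN_STEP_CM
                              ) -> tuple[Route, StepSample | None]:
    """Open-path TS route by iterated 2-opt local search.

    Starts from the NN solution, polishes with 2-opt, then repeatedly
    perturbs (double-bridge) and re-polishes, keeping improvements; the
    loop stops once the total length has failed to shorten N consecutive
    times (N = number of shoots). The result is never longer than the NN
    route.
    """
    if smap.n_shoots < 2:
        warnings.warn("single shoot: empty step sample", stacklevel=2)
        return Route(order=np.array([0]), total_length=0.0), None
    D = squareform(pdist(smap.xy))
    nn_route, _ = nearest_neighbour_route(smap, smin)
    order, length = _two_opt(nn_route.order, D)
    rng = np.random.default_rng(seed)
    n = smap.n_shoots
    fails = 0
    while fails < n:
        cand = _double_bridge(order, rng)
        cand, cand_len = _two_opt(cand, D)
        if cand_len < length - 1e-12:
            order, length = cand, cand_len
            fails = 0
        else:
            fails += 1
    route = Route(order=order, total_length=length)
    return route, route_steps(route, smap, smin, "travelling_salesman")


def validate_reconstruction(estimated: StepSample, reference: StepSample
                            ) -> tuple[float, float]:
    """Two-sample KS test of estimated vs ground-truth step distributions.

    Returns (statistic, p). p > 0.05 is read as "statistically
    indistinguishable" — the reconstruction recovers the step-size
    distribution even if individual links differ.
    """
    if estimated is None or reference is None:
        raise InvariantError("both samples must be non-empty")
    res = stats.ks_2samp(estimated.steps, reference.steps, method="asymp")
    return float(res.statistic), float(res.pvalue)


def link_recovery(route: Route, smap: ShootMap) -> float:
    """Fraction of true rhizome links present as consecutive route pairs."""
    truth = smap.true_links()
    if not truth:
        raise InvariantError("map has no ground-truth links")
    return len(truth & route.links()) / len(truth)
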