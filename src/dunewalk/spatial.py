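"""Point-pattern characterization of shoot maps.

Two complementary summaries: Ripley's K/L function tests departure from
complete spatial randomness (clustering vs dispersion at each scale), and
the box-counting fractal dimension quantifies the scale-free patchiness
("Levy dust") that a heavy-tailed expansion walk leaves behind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import InvariantError, ShootMap


@dataclass
class FractalResult:
    box_sizes: np.ndarray      # cm
    counts: np.ndarray         # occupied boxes per size
    fit_range: tuple[float, float]
    Df: float                  # slope magnitude of log N(s) vs log s
    r2: float


@dataclass
class RipleyResult:
    radii: np.ndarray
    K: np.ndarray
    L: np.ndarray
    classification: np.ndarray  # 'clustered' | 'dispersed' | 'csr' per radius


def box_sizes_for_range(side: float, fit_range: tuple[float, float]) -> np.ndarray:
    """Box sizes that partition a square of the given side exactly.

    Sizes are side/k for every integer k with side/k inside ``fit_range``,
    so no partial boundary boxes exist at any scale (partial boxes at the
    window edge flatten the count curve and bias the slope low).
    """
    lo, hi = fit_range
    if not (0 < lo < hi):
        raise InvariantError(f"bad fit range {fit_range}")
    k_min = max(int(np.ceil(side / hi)), 1)
    k_max = int(np.floor(side / lo))
    n_sizes = k_max - k_min + 1
    if n_sizes < 3:
        raise InvariantError(
            f"pattern extent {side:.3g} cm admits fewer than 3 box sizes in "
            f"{fit_range}; pattern too small for this fit range")
    if n_sizes < 5:
        warnings.warn(f"only {n_sizes} box sizes available in {fit_range} "
                      f"for a {side:.3g} cm pattern; Df estimate is coarse",
                      stacklevel=3)
    return side / np.arange(k_max, k_min - 1, -1)


def box_count_dimension(smap: ShootMap,
                        fit_range: tuple[float, float] = (4.0, 16.0),
                        average_origins: bool = False,
                        n_origins: int = 8) -> FractalResult:
    """Box-counting fractal dimension of the shoot pattern.

    The pattern's bounding square is partitioned exactly into k x k boxes
    for every admissible integer k; a box is occupied if it holds at least
    one shoot centre. Df is the negated least-squares slope of
    log N(s) ~ log s over ``fit_range``. With ``average_origins`` the count
    at each size is instead averaged over shifted grid anchors (one extra
    boundary box per axis), trading the exact partition for an estimate
    that is insensitive to the anchor.
    """
    xy = smap.xy
    if smap.n_shoots < 10:
        raise InvariantError("box counting needs at least 10 shoots")
    span = xy.max(axis=0) - xy.min(axis=0)
    if np.all(span == 0):
        raise InvariantError("degenerate pattern: all shoots coincide")
    side = float(span.max())
    sizes = box_sizes_for_range(side, fit_range)
    lo = xy.min(axis=0)
    counts = np.empty(sizes.size)
    for k, s in enumerate(sizes):
        nbox = int(round(side / s))
        if average_origins:
            c = 0.0
            for j in range(n_origins):
                shift = lo - s * j / n_origins
                idx = np.floor((xy - shift) / s).astype(np.int64)
                c += np.unique(idx, axis=0).shape[0]
            counts[k] = c / n_origins
        else:
            idx = np.minimum(np.floor((xy - lo) / s).astype(np.int64), nbox - 1)
            counts[k] = np.unique(idx, axis=0).shape[0]
    logs, logn = np.log(sizes), np.log(counts)
    slope, intercept = np.polyfit(logs, logn, 1)
    resid = logn - (slope * logs + intercept)
    ss_tot = np.sum((logn - logn.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return FractalResult(box_sizes=sizes, counts=counts,
                         fit_range=tuple(fit_range), Df=float(-slope), r2=float(r2))


def _isotropic_weights(xy: np.ndarray, d: np.ndarray,
                       window: tuple[float, float, float, float]) -> np.ndarray:
    """Ripley's isotropic edge-correction weights for a rectangular window.

    For each point i and pair distance d_ij, the weight is 2*pi over the
    angle of the circle (centre x_i, radius d_ij) that lies inside the
    window — the standard closed-form rectangle correction.
    """
    xmin, xmax, ymin, ymax = window
    dl = xy[:, 0] - xmin
    dr = xmax - xy[:, 0]
    db = xy[:, 1] - ymin
    dt = ymax - xy[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(d > 0, d, np.inf)
        aL = np.arccos(np.minimum(dl[:, None] / r, 1.0))
        aR = np.arccos(np.minimum(dr[:, None] / r, 1.0))
        aB = np.arccos(np.minimum(db[:, None] / r, 1.0))
        aT = np.arccos(np.minimum(dt[:, None] / r, 1.0))
    ext = 2.0 * (aL + aR + aB + aT)
    for ax, ay in ((aL, aB), (aL, aT), (aR, aB), (aR, aT)):
        ext -= np.maximum(0.0, ax + ay - 0.5 * np.pi)
    frac = 1.0 - ext / (2.0 * np.pi)
    return 1.0 / np.maximum(frac, 1e-12)


def ripley_L(smap: ShootMap, radii: np.ndarray | None = None,
             edge_correction: str = "isotropic") -> RipleyResult:
    """Ripley's K and normalized L for the shoot pattern.

    The observation window is the pattern's bounding box. L(r) > r flags
    clustering at scale r, L(r) < r dispersion. Radii above half the
    window's short side are trimmed (the edge correction is unreliable
    there).
    """
    if smap.n_shoots < 10:
        raise InvariantError("Ripley's K needs at least 10 shoots")
    if edge_correction not in ("isotropic", "none"):
        raise InvariantError(f"unknown edge correction {edge_correction!r}")
    xy = smap.xy
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    window = (xmin, xmax, ymin, ymax)
    short = min(xmax - xmin, ymax - ymin)
    if short <= 0:
        raise InvariantError("degenerate window: collinear or coincident shoots")
    if radii is None:
        radii = np.linspace(0.0, short / 4.0, 51)[1:]
    radii = np.asarray(radii, dtype=float)
    keep = radii <= short / 2.0
    if not np.all(keep):
        warnings.warn("trimming radii above half the window's short side", stacklevel=2)
        radii = radii[keep]

    n = smap.n_shoots
    area = (xmax - xmin) * (ymax - ymin)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    if edge_correction == "isotropic":
        w = _isotropic_weights(xy, d, window)
    else:
        w = np.ones_like(d)
    np.fill_diagonal(w, 0.0)
    order = np.argsort(d, axis=None)
    d_flat = d.ravel()[order]
    w_flat = w.ravel()[order]
    cum = np.cumsum(w_flat)
    pos = np.searchsorted(d_flat, radii, side="right") - 1
    totals = np.where(pos >= 0, cum[np.maximum(pos, 0)], 0.0)
    K = area * totals / (n * (n - 1))
    L = np.sqrt(K / np.pi)
    cls = np.where(L > radii, "clustered", np.where(L < radii, "dispersed", "csr"))
    return RipleyResult(radii=radii, K=K, L=L, classification=cls)


def csr_envelope(n: int, window: tuple[float, float, float, float],
                 radii: np.ndarray, n_sims: int = 99, seed: int = 0,
                 edge_correction: str = "isotropic") -> tuple[np.ndarray, np.ndarray]:
    """Pointwise min/max envelope of L(r) - r under CSR in ``window``."""
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = window
    lo = np.full(radii.shape, np.inf)
    hi = np.full(radii.shape, -np.inf)
    for _ in range(n_sims):
        xy = np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])
        res = ripley_L(ShootMap(plant_id="csr", xy=xy), radii=radii,
                       edge_correction=edge_correction)
        dev = res.L - res.radii
        lo = np.minimum(lo, dev)
        hi = np.maximum(hi, dev)
    return lo, hi
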