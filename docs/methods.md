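# Methods

This note documents the models implemented in `dunewalk`, the parameters
that matter, the numerical choices, and what the synthetic-data generator
does and does not capture about real survey data.

## Clonal expansion as a random walk

A clonal plant expands by growing rhizomes of random length and placing a
new shoot at each rhizome's end. We model the placement sequence as a
discrete random walk in the plane. Step lengths are drawn from a truncated
Pareto distribution

f(s) = (μ−1) / (smin^(1−μ) − smax^(1−μ)) · s^(−μ),  smin ≤ s ≤ smax,

by the inverse-CDF transform
S(X) = (X·(smin^(1−μ) − smax^(1−μ)) + smax^(1−μ))^(1/(1−μ)) with X uniform
on [0,1] (X=1 gives smin, X=0 gives smax). The Lévy exponent μ controls the
strategy: μ→1 is near-ballistic, μ≈2 is the classical Lévy search optimum
producing fractal "Lévy dust" patchiness, μ→3 approaches a Brownian walk.

Defaults (plant-local Cartesian cm, y up, wind along +x):

| parameter | default | meaning |
|---|---|---|
| `mu` | 1.98 | pooled exponent of the Lévy-type strategy archetype |
| `smin` | 0.34 cm | smallest rhizome step (also the survey's positional error) |
| `smax` | 75.33 cm | largest observed rhizome step |
| `n_shoots` | 150 | shoots per plant, matching young surveyed plants |
| `p_branch` | 0.2 | probability a step starts from a random earlier shoot |
| `sigma_angle` | 0.6 rad | wrapped-normal turning-angle scale (correlated variant) |

Branching and turning-angle correlation are implemented as variants
(`compare_walk_variants`) because the shoot pattern's fractal dimension is
insensitive to both (the suite asserts their means differ by less than
replicate spread), which justifies using the plain non-branching,
uniform-angle walk everywhere else. Branching is realized as the minimal
one-parameter mechanism: with probability `p_branch` the new rhizome
originates from a uniformly chosen existing shoot instead of the current
tip. The first heading is uniform; the walk starts at the origin.

## Step-size models and selection

Five candidate models are fitted above a fixed analysis cutoff
smin = 0.68 cm — twice the positional error, below which two pins cannot be
told apart. The cutoff is a deliberate fixed choice (the goal is the model
that describes the bulk of the data, not tail identification), configurable
for sensitivity analyses.

* Brownian (null): f(s) = λ·exp(λ(smin−s)); closed-form
  λ̂ = n / Σ(sᵢ − smin).
* Lévy: Pareto f(s) = (μ−1)·smin^(μ−1)·s^(−μ); closed-form
  μ̂ = 1 + n / Σ(ln sᵢ − ln smin).
* Truncated Lévy: the density above with upper bound smax fixed at the
  sample maximum; μ̂ by bounded 1-D likelihood maximization over
  μ ∈ (1.0001, 10], with a degeneracy flag if the optimum pins at a bound.
* Composite Brownian: two-mode exponential mixture
  g(s) = w₁f₁(s) + (1−w₁)f₂(s); (w₁, λ₁, λ₂) by multi-start bounded
  L-BFGS-B (10 starts, ftol 1e−12), label symmetry broken by λ₁ > λ₂.
* Log-normal: μ_log and σ are the mean and population standard deviation
  of ln s (the standard log-normal density; its support is (0, ∞), so it
  competes without renormalization above smin).

Model comparison uses AIC = 2k − 2·loglik and Akaike weights
wAIC_i = exp(−½ΔAIC_i)/Σ exp(−½ΔAIC_k). The free-parameter ledger is
brownian 1, levy 1, truncated_levy 1 (smax is the observed maximum, not
estimated), composite_brownian 3 (2m−1 for m = 2 modes), lognormal 2.
Goodness of fit is a one-sample KS statistic against the fitted CDF; the
default p-value is asymptotic (fitted parameters make it conservative), and
a parametric-bootstrap p (refit per replicate) is available behind
`ks_pvalue="bootstrap"`.

A note on the Pareto pair: on any finite sample the truncated Lévy model,
with smax pinned at the sample maximum and the same parameter count,
dominates the unbounded Lévy likelihood. Selection between the two is
therefore meaningful only at the family level, and the test suite scores
the unbounded-Pareto generator as recovered when either family member wins.

## Network reconstruction

Two connecting algorithms estimate the rhizome route from coordinates:

* NN: a greedy nearest-neighbour chain grown from every possible start;
  the chain of minimum total length wins. Distance ties break to the lowest
  shoot index; equal-length chains break to the lowest-index start. NN is
  the pipeline default (simplest, fewest assumptions).
* TS: an open-path travelling-salesman route — 2-opt local search seeded
  at the NN solution inside an iterated local search (double-bridge
  perturbations), stopping after N consecutive non-improving perturbations
  (N = shoot count). By construction TS is never longer than NN; on all
  ≤ 8-shoot instances tested it matches the brute-force optimum.

Consecutive route distances below 0.68 cm are dropped *after* route
construction: sub-resolution pins still anchor the route, they are only
excluded from the fitted sample. Validation is distribution-level: a
two-sample KS test of reconstructed vs excavated steps (p > 0.05 read as
indistinguishable). Link-level recovery is much weaker than
distribution-level recovery — the NN route recovers ~30–40% of the true
consecutive links at μ = 2 (calibrated floor 0.30, fixed by
`scripts/calibrate_recovery.py`) while reproducing the step distribution,
because clustered patterns admit many reorderings with near-identical step
statistics.

## Spatial statistics

Ripley's K uses the rectangular bounding box as the observation window with
the standard closed-form isotropic edge correction for rectangles; radii
above half the window's short side are trimmed. L(r) = √(K(r)/π) is
classified clustered (L > r) or dispersed (L < r) per radius.

Box counting partitions the pattern's bounding square exactly into k × k
boxes for every integer k whose box size lies in the fit range, counts
boxes holding ≥ 1 shoot centre, and takes Df as the negated least-squares
slope of log N(s) vs log s. Exact partitions are used instead of a fixed
log-spaced size ladder because partial boxes at the window edge flatten the
count curve and bias Df low — with exact partitions the estimator returns
2.000 for a uniform square and 1.000 for a line, and tracks the theoretical
Lévy-dust dimension μ−1. Adjacent sizes come from non-nested grids, so
N(s) is monotone between well-separated sizes rather than between
neighbours. The default anchor is deterministic; `average_origins=True`
averages counts over shifted anchors (one extra boundary box per axis) and
is the variant that is rotation-invariant to ±0.02.

Field-style fit ranges: 4–16 cm for survey patterns (the resolvable range),
2–16 cm for model-generated patterns.

## Wind attenuation and sand capture

Each shoot sheds a downwind wake of fractional velocity deficit

deficit(x, y) = a₀ · exp(−x/Lx) · exp(−y² / (2σy(x)²)),  x ≥ 0,

with σy(x) = σy₀·√(1 + x/Lx) (wake widening), the x = 0 profile within one
shoot diameter upwind (stagnation), zero beyond, and truncation where the
deficit falls below 0.005. Wakes of all shoots add and the sum is clamped
to [0, 1]; u/u₀ = 1 − deficit, computed by FFT convolution of the
rasterized shoot grid with the kernel on a 0.5 cm grid padded by the kernel
extent (no wake is clipped). Sand deposits where u/u₀ < 0.61 of the
free-stream speed (6.5 m/s); deposition area is the sub-threshold cell
count × cell². Trapping efficiency divides that area by the mean rhizome
length between shoots — ground-truth links for simulated maps, the NN route
for observed ones, with *all* links counted including those below the
0.68 cm analysis cutoff (investment is physical, not observational).

The kernel is an analytic stand-in for a per-shoot computational-fluid-
dynamics wake; a file-load path (`kernel_path`) accepts externally computed
kernels on the same grid. The defaults a₀ = 0.65, Lx = 12 cm,
σy₀ = 1.2 cm were fixed once by `scripts/calibrate_kernel.py` against the
qualitative behaviour the model is built to express — deposition area
maximal at the dispersed end (μ ≈ 1.5) and efficiency maximal at the Lévy
optimum (μ ≈ 2) for ~1000-shoot networks, robust across seed batches — and
are physically plausible (a strong near-wake deficit behind a 1.5 mm
cylinder, decaying over ~80 diameters). The qualitative orderings hold
across deposition thresholds 0.25–0.85 (read as fractions of the incoming
speed) and strengthen with shoot number: below a few hundred shoots the
clumped strategy (μ ≈ 3) is the most efficient, the Lévy strategy takes
over from ~1000 shoots.

The planting-layout emulation places domain-confined walks
(μ = 1.1 / 2.0 / 3.0 for dispersed / patchy / single-patch) of ~2000 shoots
in a 2 m × 2 m plot (500 shoots m⁻²). Across replicate seeds the dispersed
layout traps the largest area and the patchy layout is the most efficient
on average; the single-patch layout's efficiency is closer to patchy here
than in a physical planting, because a walk-based single patch has a very
short mean rhizome length in the denominator.

## The synthetic survey generator

`make_survey_plant` degrades a simulated walk the way the pin-mapping
protocol degrades a real plant: isotropic Gaussian jitter of 0.34 cm on
every shoot, then repeated closest-pair merging below 0.68 cm (midpoint
replacement with parent-link remapping). Archetype cohorts:
`arenaria_like` draws truncated-Pareto steps at μ = 1.98;
`breviligulata_like` draws from a two-mode exponential mixture
(w₁, λ₁, λ₂) = (0.6, 1.5, 0.08), calibrated once
(`scripts/calibrate_mixture.py`) so its large-sample truncated-Lévy shadow
lands near μ = 1.5 while composite Brownian wins the selection.

What passing tests show — and what they do not. The generator reproduces
the measurement artefacts (jitter, resolution merging) but not biology the
walk model omits: no shoot mortality, no directional bias from dunes or
prevailing wind, no tiller clusters, no multi-plant interleaving. Two
calibrated facts about the pipeline follow from the generator and are
asserted as such: (i) NN reconstruction on *raw* walks recovers the pooled
exponent without bias (μ̂ = 2.0 ± 0.15 at 8 × 150 shoots); (ii) the *full*
survey degradation adds an upward bias of roughly +0.2–0.3 to the pooled
μ̂ (bounded at +0.35 in the suite), because merging followed by NN routing
manufactures many near-cutoff steps. Estimates from resolution-limited
survey maps should be read with that asymmetry in mind.

## Numerical choices and degenerate inputs

* All stochastic operations take an explicit integer seed; result files
  carry a JSON sidecar with config, seed and package version, and tables
  round-trip at 12 significant digits.
* Truncated-Lévy maximization: `scipy.optimize.minimize_scalar` (bounded,
  xatol 1e−10); agreement with a 10⁵-point grid search to 1e−3 is asserted
  on a shipped 20-step fixture, and the closed-form estimators agree with
  independent numerical maximizers to 1e−6.
* Mixture fitting: log-sum-exp likelihood; non-convergence of all starts
  flags the fit degenerate instead of raising.
* Degenerate samples (all steps at smin, zero log-variance, n below a
  model's minimum) produce flagged `FitResult`s with reasons; selection
  requires ≥ 2 non-degenerate fits.
* Wind convolution equals per-shoot brute-force summation to 1e−9; results
  are exactly invariant under whole-map translation (the grid is anchored
  to the pattern).
* Single-shoot maps have undefined mean step; efficiency is reported as
  NaN rather than inferred.

## Problem sizes

The default test run uses desk-scale problem sizes chosen to exercise every
claim: 10⁵ draws for sampler KS checks, 100 × n = 1000 replicates for
estimator recovery and selection accuracy, 200 brute-force instances
(≤ 8 shoots) for TS optimality, 7 × 150-shoot walks for fractal dimension,
and 1000-shoot networks × 4 replicates for the deposition sweep. The
acceptance script runs the efficiency sweep at the full 4000-shoot, 8-replicate
scale (a few seconds via FFT convolution).

## Known limitations

* The wake model is kinematic superposition with clamping — no momentum
  conservation, sheltering nonlinearity, or topography feedback; it is a
  proxy for *potential* deposition area, not a sediment-transport model.
* The box-count Df of model walks at μ = 1.98 over 2–16 cm sits near 0.9
  (consistent with the theoretical dust dimension μ−1 = 0.98); estimators
  that include sub-resolution scales report materially lower values, so Df
  values are comparable only under an identical counting protocol.
* Ripley's K assumes a rectangular window equal to the bounding box; very
  elongated patterns make the isotropic correction coarse.
* The TS stopping rule ("no improvement for N perturbations") trades
  guaranteed optimality for determinism at fixed seed; optimality is
  verified only for small instances.
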