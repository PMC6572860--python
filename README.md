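# dunewalk

Heavy-tailed clonal-expansion analysis for dune-building grasses: reconstruct
rhizome networks from mapped shoot coordinates, fit and select among
heavy-tailed step-size models, characterize the spatial shoot pattern, and
score shoot configurations for wind-driven sand capture.

## The scientific problem

Beach grasses such as *Ammophila* colonize bare sand by clonal expansion:
a plant repeatedly grows a belowground rhizome of random length and places a
new shoot at its end. The sequence of inter-shoot placements is a random
walk, and the walk's step-size distribution is the plant's *expansion
strategy*. Strategies differ in how they balance two needs — covering area
(long steps) and building dense, wind-calming shoot patches (short steps) —
and that balance controls how effectively a young plant traps wind-blown
sand and starts a dune.

`dunewalk` provides the full analysis chain for this question:

1. **Walk model** (`walk`): a discrete random walk with truncated-Pareto
   steps, drawn by inverse CDF

   S(X) = (X·(smin^(1−μ) − smax^(1−μ)) + smax^(1−μ))^(1/(1−μ)),  X ~ U(0,1),

   with Lévy exponent 1 < μ ≤ 3 (μ→1 ballistic, μ≈2 Lévy optimum, μ→3
   Brownian-like), optional branching and correlated turning angles.
2. **Network reconstruction** (`reconstruct`): nearest-neighbour (NN) and
   open-path travelling-salesman (TS) routes estimate the step-size
   distribution from shoot coordinates alone; a two-sample KS test
   validates against excavated ground truth.
3. **Step-size model selection** (`models`): maximum-likelihood fits of
   Brownian f(s) = λe^(λ(smin−s)), Lévy f(s) ∝ s^(−μ), truncated Lévy
   f(s) = (μ−1)/(smin^(1−μ) − smax^(1−μ)) · s^(−μ), two-mode composite
   Brownian g(s) = w₁f₁(s) + (1−w₁)f₂(s), and log-normal; ranked by Akaike
   weights wAIC_i = exp(−½ΔAIC_i) / Σ_k exp(−½ΔAIC_k), with one-sample KS
   goodness of fit.
4. **Spatial statistics** (`spatial`): Ripley's L(r) = √(K(r)/π) with
   isotropic edge correction (clustered where L(r) > r), and the
   box-counting fractal dimension Df (slope magnitude of log N(s) vs log s).
5. **Wind capture** (`wind`): a gridded wind-attenuation model that
   convolves a single-shoot wake kernel over the shoot map, thresholds wind
   speed at a deposition fraction (default 0.61 of the free stream), and
   reports deposition area and sand-trapping efficiency
   (area / mean rhizome length between shoots).
6. **Synthetic surveys** (`survey`): survey-like fixtures with positional
   jitter (0.34 cm) and sub-resolution merging (< 0.68 cm), with known
   ground truth, so the whole chain is testable without field data.

## Worked example

```python
import numpy as np
from dunewalk import StepSample, select_model, sample_step

rng = np.random.default_rng(0)
steps = sample_step(mu=2.0, smin=0.68, smax=75.33, u=rng.random(1000))
table = select_model(StepSample(steps=steps, smin=0.68, plant_id="demo"))
for f in sorted(table.fits, key=lambda f: -f.waic):
    print(f"{f.model:>20s}  AIC={f.aic:8.1f}  wAIC={f.waic:.3f}")
```

prints

```
      truncated_levy  AIC=  2843.0  wAIC=0.998
                levy  AIC=  2855.6  wAIC=0.002
  composite_brownian  AIC=  2913.1  wAIC=0.000
           lognormal  AIC=  3628.2  wAIC=0.000
            brownian  AIC=  3812.9  wAIC=0.000
```

The truncated Lévy model carries essentially all the Akaike weight and its
estimate μ̂ = 2.06 recovers the generating exponent 2.0; the Brownian null
is rejected outright. The scripts in `examples/` walk through each
capability the same way (simulation, reconstruction, spatial statistics,
the sand-trapping sweep and the planting-layout comparison) and print the
numbers they compute.

A thin CLI mirrors the library:
`dunewalk synth|reconstruct|fit|spatial|wind|sweep|experiment|survey`,
each accepting `--seed`, `--config` (YAML) and `--out`.

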