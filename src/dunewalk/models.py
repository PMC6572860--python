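"""Maximum-likelihood fitting and Akaike-weight selection of step-size models.

Five candidate models describe the distribution of rhizome step lengths
above a fixed analysis cutoff smin (0.68 cm, twice the positional
measurement error): Brownian (shifted exponential; the null), Levy (Pareto
power law), truncated Levy (Pareto bounded at the largest observed step),
two-mode composite Brownian (exponential mixture), and log-normal. Models
are compared by Akaike weights; goodness of fit uses a one-sample KS
statistic against the fitted CDF.

Free parameters counted in AIC: brownian 1 (lambda), levy 1 (mu),
truncated_levy 1 (mu; smax is pinned at the observed maximum, not
estimated), composite_brownian 3 (w1, lambda1, lambda2), lognormal 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from . import distributions as dist
from .types import (FitResult, InvariantError, SelectionTable, StepSample,
                    MIN_STEP_CM)

#: default analysis cutoff for fitting (cm)
DEFAULT_SMIN = MIN_STEP_CM

_MU_BOUNDS = (1.0001, 10.0)


@dataclass
class ModelSpec:
    """A candidate model: density, CDF, sampler and free-parameter count."""

    name: str
    k: int
    pdf: Callable  # pdf(s, params, smin, smax)
    cdf: Callable
    sample: Callable  # sample(rng, n, params, smin, smax)
    fit: Callable  # fit(StepSample) -> FitResult


# ---------------------------------------------------------------------------
# individual fits


def fit_brownian(sample: StepSample) -> FitResult:
    """Closed-form MLE of the shifted-exponential rate: lambda = n / sum(s - smin)."""
    s, smin, n = sample.steps, sample.smin, sample.n
    denom = float(np.sum(s - smin))
    if denom <= 0:
        return FitResult(model="brownian", params={"lam": np.nan}, loglik=-np.inf,
                         k=1, degenerate=True, reason="all steps equal smin")
    lam = n / denom
    loglik = n * np.log(lam) + lam * (n * smin - float(np.sum(s)))
    return FitResult(model="brownian", params={"lam": lam}, loglik=float(loglik), k=1)


def fit_levy(sample: StepSample) -> FitResult:
    """Closed-form MLE of the Pareto exponent: mu = 1 + n / sum(ln s - ln smin)."""
    s, smin, n = sample.steps, sample.smin, sample.n
    denom = float(np.sum(np.log(s) - np.log(smin)))
    if denom <= 0:
        return FitResult(model="levy", params={"mu": np.nan}, loglik=-np.inf,
                         k=1, degenerate=True, reason="all steps equal smin")
    mu = 1.0 + n / denom
    loglik = n * np.log(mu - 1.0) + n * (mu - 1.0) * np.log(smin) - mu * float(np.sum(np.log(s)))
    return FitResult(model="levy", params={"mu": mu}, loglik=float(loglik), k=1)


def trunc_levy_loglik(mu: float, sample: StepSample, smax: float | None = None) -> float:
    """Log-likelihood of the truncated-Pareto density at exponent mu."""
    smax = sample.smax if smax is None else smax
    s, smin, n = sample.steps, sample.smin, sample.n
    norm = (mu - 1.0) / (smin ** (1.0 - mu) - smax ** (1.0 - mu))
    return n * np.log(norm) - mu * float(np.sum(np.log(s)))


def fit_truncated_levy(sample: StepSample, mu_bounds=_MU_BOUNDS) -> FitResult:
    """Bounded 1-D maximization of the truncated-Pareto log-likelihood.

    smax is fixed at the sample maximum (it is the observed truncation, not
    a free parameter), so k = 1. An optimum pinned at either mu bound is
    flagged degenerate rather than returned silently.
    """
    if sample.n < 2:
        return FitResult(model="truncated_levy", params={"mu": np.nan, "smax": sample.smax},
                         loglik=-np.inf, k=1, degenerate=True, reason="n < 2")
    res = optimize.minimize_scalar(lambda m: -trunc_levy_loglik(m, sample),
                                   bounds=mu_bounds, method="bounded",
                                   options={"xatol": 1e-10})
    mu = float(res.x)
    lo, hi = mu_bounds
    if mu - lo < 1e-6 or hi - mu < 1e-6:
        return FitResult(model="truncated_levy", params={"mu": mu, "smax": sample.smax},
                         loglik=float(-res.fun), k=1, degenerate=True,
                         reason=f"optimizer at mu bound {mu:.4g}")
    return FitResult(model="truncated_levy", params={"mu": mu, "smax": sample.smax},
                     loglik=float(-res.fun), k=1)


def _mixture_nll(theta: np.ndarray, s: np.ndarray, smin: float) -> float:
    w1, lam1, lam2 = theta
    la = np.log(w1) + np.log(lam1) + lam1 * (smin - s)
    lb = np.log1p(-w1) + np.log(lam2) + lam2 * (smin - s)
    return -float(np.sum(np.logaddexp(la, lb)))


def fit_composite_brownian(sample: StepSample, n_starts: int = 10) -> FitResult:
    """Numerical MLE of the two-mode exponential mixture (w1, lambda1, lambda2).

    Multi-start bounded L-BFGS-B; label symmetry is broken by reporting the
    faster mode first (lambda1 > lambda2).
    """
    if sample.n < 10:
        return FitResult(model="composite_brownian", params={}, loglik=-np.inf,
                         k=3, degenerate=True, reason="n < 10")
    s, smin = sample.steps, sample.smin
    base = 1.0 / max(float(np.mean(s - smin)), 1e-12)
    rng = np.random.default_rng(12345)
    starts = [(0.5, base * 3.0, base / 3.0), (0.7, base * 5.0, base / 2.0),
              (0.3, base * 2.0, base / 5.0)]
    while len(starts) < n_starts:
        starts.append((rng.uniform(0.05, 0.95),
                       base * 10.0 ** rng.uniform(0, 1.5),
                       base * 10.0 ** rng.uniform(-1.5, 0)))
    bounds = [(1e-6, 1 - 1e-6), (1e-9, None), (1e-9, None)]
    best = None
    for x0 in starts:
        res = optimize.minimize(_mixture_nll, x0=np.asarray(x0), args=(s, smin),
                                method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-10})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return FitResult(model="composite_brownian", params={}, loglik=-np.inf,
                         k=3, degenerate=True, reason="no start converged")
    w1, lam1, lam2 = best.x
    if lam1 < lam2:
        w1, lam1, lam2 = 1.0 - w1, lam2, lam1
    return FitResult(model="composite_brownian",
                     params={"w1": float(w1), "lam1": float(lam1), "lam2": float(lam2)},
                     loglik=float(-best.fun), k=3)


def fit_lognormal(sample: StepSample) -> FitResult:
    """MLE of the log-normal: mean and (population) s.d. of ln(steps)."""
    logs = np.log(sample.steps)
    mu_log = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    if sigma <= 0 or sample.n < 2:
        return FitResult(model="lognormal", params={"mu_log": mu_log, "sigma": sigma},
                         loglik=-np.inf, k=2, degenerate=True,
                         reason="zero variance of log-steps")
    loglik = float(np.sum(stats.lognorm.logpdf(sample.steps, s=sigma, scale=np.exp(mu_log))))
    return FitResult(model="lognormal", params={"mu_log": mu_log, "sigma": sigma},
                     loglik=loglik, k=2)


# ---------------------------------------------------------------------------
# registry

def _sample_exp(rng, n, p, smin, smax):
    return smin + rng.exponential(1.0 / p["lam"], size=n)


def _sample_pareto(rng, n, p, smin, smax):
    return smin * (1.0 - rng.random(n)) ** (-1.0 / (p["mu"] - 1.0))


def _sample_trunc(rng, n, p, smin, smax):
    return dist.trunc_pareto_ppf(rng.random(n), p["mu"], smin, p.get("smax", smax))


def _sample_mix(rng, n, p, smin, smax):
    return dist.sample_mixture(rng, n, p["w1"], p["lam1"], p["lam2"], smin)


def _sample_logn(rng, n, p, smin, smax):
    return np.exp(rng.normal(p["mu_log"], p["sigma"], size=n))


MODELS: dict[str, ModelSpec] = {
    "brownian": ModelSpec(
        "brownian", 1,
        pdf=lambda s, p, smin, smax: dist.exp_pdf(s, p["lam"], smin),
        cdf=lambda s, p, smin, smax: dist.exp_cdf(s, p["lam"], smin),
        sample=_sample_exp, fit=fit_brownian),
    "levy": ModelSpec(
        "levy", 1,
        pdf=lambda s, p, smin, smax: dist.pareto_pdf(s, p["mu"], smin),
        cdf=lambda s, p, smin, smax: dist.pareto_cdf(s, p["mu"], smin),
        sample=_sample_pareto, fit=fit_levy),
    "truncated_levy": ModelSpec(
        "truncated_levy", 1,
        pdf=lambda s, p, smin, smax: dist.trunc_pareto_pdf(s, p["mu"], smin, p.get("smax", smax)),
        cdf=lambda s, p, smin, smax: dist.trunc_pareto_cdf(s, p["mu"], smin, p.get("smax", smax)),
        sample=_sample_trunc, fit=fit_truncated_levy),
    "composite_brownian": ModelSpec(
        "composite_brownian", 3,
        pdf=lambda s, p, smin, smax: dist.mixture_pdf(s, p["w1"], p["lam1"], p["lam2"], smin),
        cdf=lambda s, p, smin, smax: dist.mixture_cdf(s, p["w1"], p["lam1"], p["lam2"], smin),
        sample=_sample_mix, fit=fit_composite_brownian),
    "lognormal": ModelSpec(
        "lognormal", 2,
        pdf=lambda s, p, smin, smax: dist.lognormal_pdf(s, p["mu_log"], p["sigma"]),
        cdf=lambda s, p, smin, smax: dist.lognormal_cdf(s, p["mu_log"], p["sigma"]),
        sample=_sample_logn, fit=fit_lognormal),
}


# ---------------------------------------------------------------------------
# selection


def _ks_gof(fit: FitResult, sample: StepSample) -> tuple[float, float]:
    spec = MODELS[fit.model]
    res = stats.kstest(sample.steps,
                       lambda s: spec.cdf(s, fit.params, sample.smin, sample.smax))
    return float(res.statistic), float(res.pvalue)


def _ks_bootstrap_p(fit: FitResult, sample: StepSample, n_boot: int, seed: int) -> float:
    """Parametric-bootstrap KS p-value (refit per replicate, Clauset style)."""
    spec = MODELS[fit.model]
    rng = np.random.default_rng(seed)
    stat_obs, _ = _ks_gof(fit, sample)
    exceed = 0
    for _ in range(n_boot):
        s = spec.sample(rng, sample.n, fit.params, sample.smin, sample.smax)
        s = np.maximum(s, sample.smin)
        boot = StepSample(steps=s, smin=sample.smin, provenance=sample.provenance)
        bfit = spec.fit(boot)
        if bfit.degenerate:
            continue
        stat_b, _ = _ks_gof(bfit, boot)
        if stat_b >= stat_obs:
            exceed += 1
    return (exceed + 1) / (n_boot + 1)


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    d = aics - np.min(aics)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def select_model(sample: StepSample, models: Sequence[str] = tuple(MODELS),
                 ks_pvalue: str = "asymptotic", n_boot: int = 200,
                 seed: int = 0) -> SelectionTable:
    """Fit all candidates, attach AIC / Akaike weights / KS goodness of fit.

    AIC = 2k - 2 loglik; weights are the normalized relative likelihoods
    over the non-degenerate fits. ``ks_pvalue='bootstrap'`` replaces the
    asymptotic one-sample KS p with a parametric-bootstrap p.
    """
    fits = [MODELS[m].fit(sample) for m in models]
    valid = [f for f in fits if not f.degenerate]
    if len(valid) < 2:
        raise InvariantError("fewer than two non-degenerate fits; cannot select")
    w = akaike_weights(np.array([f.aic for f in valid]))
    for f, wi in zip(valid, w):
        f.waic = float(wi)
        f.ks_stat, f.ks_p = _ks_gof(f, sample)
        if ks_pvalue == "bootstrap":
            f.ks_p = _ks_bootstrap_p(f, sample, n_boot, seed)
    for f in fits:
        if f.degenerate:
            f.waic = 0.0
    return SelectionTable(sample_id=sample.plant_id or sample.provenance, fits=fits)


@dataclass
class IndividualSummary:
    """Cohort-level digest of per-plant model selection."""

    tables: list[SelectionTable]
    excluded: list[str]                 # plant_ids with n <= min_n
    mu_mean: float                      # mean truncated-Levy mu-hat
    mu_sem: float
    best_model_share: dict[str, float]  # fraction of plants per winning model


def fit_individuals(cohort: Sequence[StepSample], min_n: int = 30,
                    **select_kw) -> IndividualSummary:
    """Per-plant selection for plants with n > min_n, plus a cohort summary."""
    if not cohort:
        raise InvariantError("empty cohort")
    tables, excluded, mus, winners = [], [], [], []
    for sample in cohort:
        if sample.n <= min_n:
            excluded.append(sample.plant_id or "?")
            continue
        table = select_model(sample, **select_kw)
        tables.append(table)
        tfit = table["truncated_levy"]
        if not tfit.degenerate:
            mus.append(tfit.params["mu"])
        winners.append(table.best.model)
    if winners:
        share = {m: winners.count(m) / len(winners) for m in sorted(set(winners))}
    else:
        share = {}
    mu_mean = float(np.mean(mus)) if mus else np.nan
    mu_sem = float(np.std(mus, ddof=1) / np.sqrt(len(mus))) if len(mus) > 1 else np.nan
    return IndividualSummary(tables=tables, excluded=excluded,
                             mu_mean=mu_mean, mu_sem=mu_sem,
                             best_model_share=share)
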