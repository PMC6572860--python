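"""Analytic forms of the five candidate step-size distributions.

Supports are step lengths ``s >= smin > 0`` (cm); the truncated Pareto is
additionally bounded above at ``smax``. The log-normal is the standard
density on (0, inf), fitted to the log-transformed data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# -- shifted exponential (Brownian steps) -----------------------------------

def exp_pdf(s, lam, smin):
    s = np.asarray(s, dtype=float)
    return np.where(s >= smin, lam * np.exp(lam * (smin - s)), 0.0)


def exp_cdf(s, lam, smin):
    s = np.asarray(s, dtype=float)
    return np.where(s >= smin, 1.0 - np.exp(lam * (smin - s)), 0.0)


# -- Pareto (Levy steps) -----------------------------------------------------

def pareto_pdf(s, mu, smin):
    s = np.asarray(s, dtype=float)
    return np.where(s >= smin, (mu - 1.0) * smin ** (mu - 1.0) * s ** (-mu), 0.0)


def pareto_cdf(s, mu, smin):
    s = np.asarray(s, dtype=float)
    return np.where(s >= smin, 1.0 - (s / smin) ** (1.0 - mu), 0.0)


# -- truncated Pareto (truncated Levy steps) ---------------------------------

def trunc_pareto_pdf(s, mu, smin, smax):
    s = np.asarray(s, dtype=float)
    norm = (mu - 1.0) / (smin ** (1.0 - mu) - smax ** (1.0 - mu))
    out = norm * s ** (-mu)
    return np.where((s >= smin) & (s <= smax), out, 0.0)


def trunc_pareto_cdf(s, mu, smin, smax):
    s = np.asarray(np.clip(s, smin, smax), dtype=float)
    a, b = smin ** (1.0 - mu), smax ** (1.0 - mu)
    return (a - s ** (1.0 - mu)) / (a - b)


def trunc_pareto_ppf(u, mu, smin, smax):
    """Inverse CDF; u=0 maps to smax and u=1 to smin (survival convention)."""
    u = np.asarray(u, dtype=float)
    a, b = smin ** (1.0 - mu), smax ** (1.0 - mu)
    return (u * (a - b) + b) ** (1.0 / (1.0 - mu))


def trunc_pareto_mean(mu, smin, smax):
    a, b = smin ** (1.0 - mu), smax ** (1.0 - mu)
    if abs(mu - 2.0) < 1e-12:
        num = np.log(smax / smin)
    else:
        num = (smax ** (2.0 - mu) - smin ** (2.0 - mu)) / (2.0 - mu)
    return (mu - 1.0) * num / (a - b)


def trunc_pareto_var(mu, smin, smax):
    a, b = smin ** (1.0 - mu), smax ** (1.0 - mu)
    if abs(mu - 3.0) < 1e-12:
        num = np.log(smax / smin)
    else:
        num = (smax ** (3.0 - mu) - smin ** (3.0 - mu)) / (3.0 - mu)
    m1 = trunc_pareto_mean(mu, smin, smax)
    m2 = (mu - 1.0) * num / (a - b)
    return m2 - m1 ** 2


# -- two-mode exponential mixture (composite Brownian steps) ------------------

def mixture_pdf(s, w1, lam1, lam2, smin):
    return w1 * exp_pdf(s, lam1, smin) + (1.0 - w1) * exp_pdf(s, lam2, smin)


def mixture_cdf(s, w1, lam1, lam2, smin):
    return w1 * exp_cdf(s, lam1, smin) + (1.0 - w1) * exp_cdf(s, lam2, smin)


def sample_mixture(rng, n, w1, lam1, lam2, smin):
    lam = np.where(rng.random(n) < w1, lam1, lam2)
    return smin + rng.exponential(1.0, size=n) / lam


# -- log-normal ---------------------------------------------------------------

def lognormal_pdf(s, mu_log, sigma):
    return stats.lognorm.pdf(s, s=sigma, scale=np.exp(mu_log))


def lognormal_cdf(s, mu_log, sigma):
    return stats.lognorm.cdf(s, s=sigma, scale=np.exp(mu_log))
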