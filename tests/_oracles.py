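"""Independent oracles used by the test suite.

These deliberately avoid the vectorized implementation paths they
check: plain Python loops, the classical rank formula, and closed-form
Gaussian expectations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata


def brute_force_attribution(cube_values, dates, curve, rate):
    """Per-cell per-day AN by a plain Python loop over scalars."""
    n_days, nr, nc = cube_values.shape
    out = np.empty((n_days, nr, nc))
    for d in range(n_days):
        diy = 366 if dates[d].is_leap_year else 365
        for i in range(nr):
            for j in range(nc):
                rr = max(float(curve.rr(cube_values[d, i, j])), 1.0)
                af = (rr - 1.0) / rr
                out[d, i, j] = af * rate / diy
    return out


def spearman_rank_formula(x, y):
    """Spearman rho via Pearson correlation of the ranks (mid-ranks for
    ties), computed from first principles."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def _exp_indicator_above(a, mu, sigma, c):
    """E[exp(a·T)·1{T > c}] for T ~ N(mu, sigma²)."""
    return np.exp(a * mu + 0.5 * a * a * sigma * sigma) * norm.cdf(
        (mu + a * sigma * sigma - c) / sigma
    )


def _exp_indicator_below(a, mu, sigma, c):
    return np.exp(a * mu + 0.5 * a * a * sigma * sigma) * norm.cdf(
        (c - mu - a * sigma * sigma) / sigma
    )


def expected_af_linear(mu, sigma, mmt, beta_cold, beta_warm):
    """E[AF(T)] for T ~ N(mu, sigma²) under a V-shaped piecewise-linear
    log-RR curve: log RR = beta_warm·(T−MMT) above the MMT and
    beta_cold·(MMT−T) below it.

    AF = 1 − exp(−log RR); both branch expectations are lognormal
    partial moments, available in closed form.
    """
    warm = np.exp(beta_warm * mmt) * _exp_indicator_above(-beta_warm, mu, sigma, mmt)
    cold = np.exp(-beta_cold * mmt) * _exp_indicator_below(beta_cold, mu, sigma, mmt)
    return 1.0 - warm - cold
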