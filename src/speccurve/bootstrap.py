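"""Bias-corrected and accelerated (BCa) bootstrap confidence intervals."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["bca_ci"]


def _bca_endpoints(theta_hat, boot, jack, level):
    """Combine bootstrap replicates and jackknife values into a BCa interval.

    Returns (lower, upper, z0, a).
    """
    boot = np.asarray(boot, dtype=float)
    B = boot.size
    if np.allclose(boot, boot[0]):
        warnings.warn("degenerate bootstrap distribution; returning a "
                      "point interval", stacklevel=3)
        return float(boot[0]), float(boot[0]), 0.0, 0.0
    frac = np.count_nonzero(boot < theta_hat) / B
    frac = np.clip(frac, 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(frac)
    jack = np.asarray(jack, dtype=float)
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0
    zalpha = stats.norm.ppf([(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    adj = stats.norm.cdf(z0 + (z0 + zalpha) / (1.0 - a * (z0 + zalpha)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi), float(z0), float(a)


def bca_ci(data, statistic, B=1000, level=0.95, seed=None,
           return_diagnostics=False):
    """BCa bootstrap confidence interval for ``statistic(data)``.

    Parameters
    ----------
    data : array-like
        Observations; resampling is over the first axis.
    statistic : callable
        Maps an array of observations to a scalar.
    B : int
        Number of bootstrap resamples (>= 2).
    level : float
        Confidence level, e.g. 0.95.
    seed : int or numpy Generator, optional
    return_diagnostics : bool
        If True, also return ``(z0, a, boot_replicates)``.

    Notes
    -----
    The bias constant is ``z0 = Phi^-1(#{theta* < theta_hat}/B)`` and the
    acceleration ``a`` comes from the jackknife third-moment formula; the
    interval endpoints are bootstrap quantiles at the adjusted levels
    ``Phi(z0 + (z0 +- z_alpha)/(1 - a (z0 +- z_alpha)))``.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    data = np.asarray(data)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(data))
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot[b] = statistic(data[idx])
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(data[mask])
        mask[i] = True
    lo, hi, z0, a = _bca_endpoints(theta_hat, boot, jack, level)
    if return_diagnostics:
        return (lo, hi), (z0, a, boot)
    return lo, hi
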