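"""Estimation statistics: BCa bootstrap intervals and Holm adjustment.

The bias-corrected and accelerated (BCa) bootstrap interval adjusts the
percentile interval for median bias (z0, from the fraction of the bootstrap
distribution below the point estimate) and for the statistic's skewness
(acceleration ``a``, from the jackknife).  The full resampled distribution
is returned so downstream code can draw the "distribution of likelihood"
panels common in estimation-statistics plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["BootstrapResult", "bca_ci", "paired_mean_difference", "holm_adjust"]


@dataclass
class BootstrapResult:
    """Point estimate, BCa interval and the resampled sampling distribution."""

    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    distribution: np.ndarray
    seed: int | None
    alpha: float = 0.05
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.distribution.size != self.n_boot:
            raise ValueError("distribution length must equal n_boot")

    def to_dict(self) -> dict:
        return {
            "point_estimate": float(self.point_estimate),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_boot": int(self.n_boot),
            "alpha": float(self.alpha),
            "seed": self.seed,
            "flags": list(self.flags),
        }


def _bootstrap_distribution(x: np.ndarray, statistic, n_boot: int,
                            rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    try:  # fast path for axis-aware statistics (np.mean, np.median, ...)
        boot = np.asarray(statistic(x[idx], axis=1), dtype=float)
        if boot.shape != (n_boot,):
            raise TypeError
    except TypeError:
        boot = np.array([statistic(x[i]) for i in idx], dtype=float)
    return boot


def bca_ci(sample, statistic=np.mean, n_boot: int = 5000, alpha: float = 0.05,
           seed: int | None = None) -> BootstrapResult:
    """BCa bootstrap confidence interval for ``statistic(sample)``.

    Parameters
    ----------
    sample : array-like, n >= 3, finite
    statistic : callable
        Applied to 1-D resamples; statistics accepting an ``axis`` keyword
        (``np.mean`` etc.) use a vectorized fast path.
    n_boot : int
        Number of bootstrap resamples (study convention: 5000).
    alpha : float
        Two-sided miss probability (0.05 -> 95 % interval).
    seed : int, optional
        Seed for the resampling generator; seeded runs are bit-reproducible.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("sample must be 1-D with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    theta = float(statistic(x))
    if not np.isfinite(theta):
        raise ValueError("statistic is not finite on the sample")

    rng = np.random.default_rng(seed)
    boot = _bootstrap_distribution(x, statistic, n_boot, rng)

    if np.ptp(boot) == 0.0:
        return BootstrapResult(theta, boot[0], boot[0], n_boot, boot, seed, alpha,
                               flags=["degenerate_bootstrap_distribution"])

    # bias correction: median position of the estimate in the bootstrap cloud
    p0 = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / n_boot
    p0 = np.clip(p0, 0.5 / n_boot, 1.0 - 0.5 / n_boot)
    z0 = sps.norm.ppf(p0)

    # acceleration from jackknife skewness
    n = x.size
    idx = np.arange(n)
    try:
        loo = x[np.stack([np.delete(idx, i) for i in range(n)])]
        jack = np.asarray(statistic(loo, axis=1), dtype=float)
        if jack.shape != (n,):
            raise TypeError
    except TypeError:
        jack = np.array([statistic(np.delete(x, i)) for i in range(n)], dtype=float)
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    a = np.sum(d**3) / (6.0 * denom) if denom > 0 else 0.0

    z_lo, z_hi = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    def _adj(z):
        return sps.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    q_lo, q_hi = _adj(z_lo), _adj(z_hi)
    ci_low, ci_high = np.quantile(boot, [q_lo, q_hi])
    return BootstrapResult(theta, float(ci_low), float(ci_high), n_boot, boot, seed, alpha)


def paired_mean_difference(a, b, n_boot: int = 5000, seed: int | None = None,
                           alpha: float = 0.05) -> BootstrapResult:
    """BCa interval on ``mean(a - b)`` for paired observations.

    The returned ``distribution`` holds the resampled mean differences for
    plotting the sampling distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D paired samples")
    return bca_ci(a - b, statistic=np.mean, n_boot=n_boot, alpha=alpha, seed=seed)


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj_sorted = np.minimum(1.0, np.maximum.accumulate((m - np.arange(m)) * p[order]))
    out = np.empty(m)
    out[order] = adj_sorted
    return out
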