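"""Vectorized replicate engine for the Monte-Carlo studies.

Everything here operates on a (reps, n) matrix of paths at once; the scalar
API in rank_stats / longrun / testing is the reference, and the test suite
pins exact agreement between the two routes.  Only Spearman statistics are
vectorized — Kendall spot checks in the studies go through the scalar path.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

from .longrun import BandwidthRule, KernelSpec
from .simulate import VAR1Config, VMAConfig, _cov_factor, _innovation_cov

__all__ = [
    "batch_simulate_var1",
    "batch_simulate_vma",
    "batch_spearman_rho",
    "batch_sigma2",
    "batch_spearman_test",
]


def batch_simulate_var1(cfg: VAR1Config, reps: int, rng: np.random.Generator):
    """Simulate ``reps`` independent stationary Model 1 paths -> (X, Y) of shape (reps, n)."""
    chol_state = _cov_factor(cfg.stationary_cov())
    chol_innov = _cov_factor(_innovation_cov(cfg.rho))
    n = cfg.n
    state = rng.standard_normal((reps, 2)) @ chol_state.T
    innov = rng.standard_normal((reps, n, 2)) @ chol_innov.T
    phi = np.array([cfg.phi_x, cfg.phi_y])
    out = np.empty((reps, n, 2))
    for i in range(n):
        state = phi * state + innov[:, i, :]
        out[:, i, :] = state
    return out[:, :, 0], out[:, :, 1]


def batch_simulate_vma(cfg: VMAConfig, reps: int, rng: np.random.Generator):
    """Simulate ``reps`` Model 2 paths -> (X, Y) of shape (reps, n)."""
    m = cfg.n + 2 * cfg.q
    if cfg.independent_t:
        innov = rng.standard_t(cfg.nu, size=(reps, m, 2))
    else:
        z = rng.standard_normal((reps, m, 2)) @ _cov_factor(_innovation_cov(cfg.rho)).T
        w = rng.chisquare(cfg.nu, size=(reps, m))
        innov = z * np.sqrt(cfg.nu / w)[:, :, None]
    if cfg.q == 0:
        return innov[:, :, 0], innov[:, :, 1]
    window = 2 * cfg.q + 1
    csum = np.cumsum(innov, axis=1)
    pad = np.zeros((reps, 1, 2))
    csum = np.concatenate([pad, csum], axis=1)
    out = (csum[:, window:, :] - csum[:, :-window, :]) / window
    return out[:, :, 0], out[:, :, 1]


def _center_ranks(a: np.ndarray) -> np.ndarray:
    r = rankdata(a, method="average", axis=1)
    return r - (a.shape[1] + 1) / 2.0


def batch_spearman_rho(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman cross-correlation of two (reps, n) matrices."""
    cx, cy = _center_ranks(x), _center_ranks(y)
    num = np.sum(cx * cy, axis=1)
    den = np.sqrt(np.sum(cx * cx, axis=1) * np.sum(cy * cy, axis=1))
    return num / den


def batch_sigma2(
    x: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec | None = None,
    bandwidth: BandwidthRule | None = None,
) -> np.ndarray:
    """Row-wise kernel long-run variance estimate with the 1/n positivity floor."""
    kernel = kernel or KernelSpec.quartic()
    bandwidth = bandwidth or BandwidthRule.auto()
    n = x.shape[1]
    bn = bandwidth.resolve(n)
    cx, cy = _center_ranks(x), _center_ranks(y)
    ssx = np.sum(cx * cx, axis=1)
    ssy = np.sum(cy * cy, axis=1)
    sigma2 = np.ones(x.shape[0])
    for h in range(1, n - 1):
        w = kernel.fn(h / bn)
        if w == 0.0:
            continue
        ax = np.sum(cx[:, : n - h] * cx[:, h:], axis=1) / ssx
        ay = np.sum(cy[:, : n - h] * cy[:, h:], axis=1) / ssy
        sigma2 += 2.0 * w * ax * ay
    return np.where(sigma2 > 0.0, sigma2, 1.0 / n)


def batch_spearman_test(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    alpha: float = 0.05,
    kernel: KernelSpec | None = None,
    bandwidth: BandwidthRule | None = None,
):
    """Row-wise two-sided Spearman test -> (rho_hat, statistic, reject)."""
    n = x.shape[1]
    rho = batch_spearman_rho(x, y)
    if method == "classical":
        sigma2 = np.full(x.shape[0], n / (n - 1.0))
    elif method == "modified":
        sigma2 = batch_sigma2(x, y, kernel, bandwidth)
    else:
        raise ValueError(f"unknown method {method!r}")
    t = np.sqrt(n) * rho / np.sqrt(sigma2)
    z = norm.ppf(1.0 - alpha / 2.0)
    return rho, t, np.abs(t) > z
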