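"""Stochastic simulators for the two study models.

Model 1 is a diagonal bivariate VAR(1) with correlated Gaussian innovations:

    (X_i, Y_i)' = diag(phi_x, phi_y) (X_{i-1}, Y_{i-1})' + (eps_i, delta_i)',
    (eps, delta) ~ N(0, [[1, rho], [rho, 1]]).

Paths are strictly stationary from the first observation: the initial state is
drawn from the exact stationary bivariate normal (component variances
``1/(1-phi^2)``, cross-covariance ``rho/(1-phi_x phi_y)``) rather than burnt in.
The population Spearman cross-correlation is ``(6/pi) asin(rho/2)``.

Model 2 is an equal-weight vector moving average of 2q+1 consecutive bivariate-t
innovations — a stand-in for smoothed series.  Small degrees of freedom give
heavy-tailed marginals; for nu <= 2 the Pearson cross-correlation does not
exist while the rank correlations remain well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm, t as t_dist

from .rank_stats import PairedSeries

__all__ = [
    "VAR1Config",
    "VMAConfig",
    "MONOTONE_MAPS",
    "simulate_var1",
    "simulate_vma",
    "sample_bivariate_t",
    "true_spearman_var1",
    "transform_marginals",
]


def true_spearman_var1(rho: float) -> float:
    """Population Spearman cross-correlation of Model 1: (6/pi) asin(rho/2)."""
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


# Strictly increasing marginal maps; rank statistics are invariant under all of them.
MONOTONE_MAPS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda v: v,
    "exp": np.exp,
    "cube": lambda v: v ** 3,
    "affine": lambda v: 2.5 * v + 7.0,
    # Gaussian quantile -> Student-t(3) quantile map, preserving the copula.
    "normal_to_t3": lambda v: t_dist.ppf(norm.cdf(v), df=3),
}


def _innovation_cov(rho: float) -> np.ndarray:
    return np.array([[1.0, rho], [rho, 1.0]])


@dataclass(frozen=True)
class VAR1Config:
    """Model 1 parameters: AR coefficients, innovation correlation, length, seed."""

    phi_x: float = 0.0
    phi_y: float = 0.0
    rho: float = 0.0
    n: int = 100
    seed: int | None = None
    marginal_transform: str | None = None
    burn_in: int = 0

    def __post_init__(self):
        if not (abs(self.phi_x) < 1 and abs(self.phi_y) < 1):
            raise ValueError(f"stationarity requires |phi| < 1, got ({self.phi_x}, {self.phi_y})")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if self.n < 3:
            raise ValueError(f"need n >= 3, got {self.n}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")

    def stationary_cov(self) -> np.ndarray:
        """Exact stationary covariance of the state (closed form)."""
        vx = 1.0 / (1.0 - self.phi_x ** 2)
        vy = 1.0 / (1.0 - self.phi_y ** 2)
        cxy = self.rho / (1.0 - self.phi_x * self.phi_y)
        return np.array([[vx, cxy], [cxy, vy]])


@dataclass(frozen=True)
class VMAConfig:
    """Model 2 parameters: half-window q, t degrees of freedom, innovation correlation."""

    q: int = 0
    nu: float = 4.0
    rho: float = 0.0
    n: int = 100
    seed: int | None = None
    independent_t: bool = False
    marginal_transform: str | None = None

    def __post_init__(self):
        if self.q < 0:
            raise ValueError(f"q must be non-negative, got {self.q}")
        if not self.nu > 0:
            raise ValueError(f"nu must be positive, got {self.nu}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if self.n < 3:
            raise ValueError(f"need n >= 3, got {self.n}")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a covariance matrix; tolerates the singular |rho|=1 edge."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def simulate_var1(cfg: VAR1Config) -> PairedSeries:
    """Simulate one strictly stationary Model 1 path."""
    rng = _rng(cfg.seed)
    chol_state = _cov_factor(cfg.stationary_cov())
    chol_innov = _cov_factor(_innovation_cov(cfg.rho)) if abs(cfg.rho) < 1 else None
    total = cfg.n + cfg.burn_in

    state = chol_state @ rng.standard_normal(2)
    z = rng.standard_normal((total, 2))
    if chol_innov is not None:
        innov = z @ chol_innov.T
    else:  # |rho| == 1: perfectly (anti)correlated innovations
        innov = np.column_stack([z[:, 0], np.sign(cfg.rho) * z[:, 0]])
    phi = np.array([cfg.phi_x, cfg.phi_y])
    out = np.empty((total, 2))
    for i in range(total):
        state = phi * state + innov[i]
        out[i] = state
    out = out[cfg.burn_in :]
    p = PairedSeries(out[:, 0], out[:, 1])
    if cfg.marginal_transform:
        p = transform_marginals(p, cfg.marginal_transform)
    return p


def sample_bivariate_t(
    nu: float,
    rho: float,
    m: int,
    seed=None,
    independent: bool = False,
) -> np.ndarray:
    """Draw ``m`` bivariate-t innovations, shape (m, 2).

    Elliptical construction ``Z * sqrt(nu / W)`` with ``Z ~ N(0, Sigma)`` and
    ``W ~ chi2_nu`` shared by both coordinates.  With ``independent=True`` the
    coordinates are two independent univariate t draws instead (separate
    mixing variables), which is genuine pairwise independence — the elliptical
    rho=0 case is uncorrelated but not independent.
    """
    if not nu > 0:
        raise ValueError(f"nu must be positive, got {nu}")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    rng = _rng(seed)
    if independent:
        return rng.standard_t(nu, size=(m, 2))
    z = rng.standard_normal((m, 2)) @ np.linalg.cholesky(_innovation_cov(rho)).T
    w = rng.chisquare(nu, size=m)
    return z * np.sqrt(nu / w)[:, None]


def simulate_vma(cfg: VMAConfig) -> PairedSeries:
    """Simulate one Model 2 path: equal-weight MA(2q) filter of t innovations.

    ``n + 2q`` innovation pairs are drawn so every output has a full window;
    q = 0 returns the innovations themselves (an iid process).
    """
    rng = _rng(cfg.seed)
    window = 2 * cfg.q + 1
    innov = sample_bivariate_t(cfg.nu, cfg.rho, cfg.n + 2 * cfg.q, rng, independent=cfg.independent_t)
    if cfg.q == 0:
        out = innov
    else:
        kern = np.full(window, 1.0 / window)
        out = np.column_stack(
            [np.convolve(innov[:, 0], kern, mode="valid"), np.convolve(innov[:, 1], kern, mode="valid")]
        )
    p = PairedSeries(out[:, 0], out[:, 1])
    if cfg.marginal_transform:
        p = transform_marginals(p, cfg.marginal_transform)
    return p


def transform_marginals(p: PairedSeries, name: str) -> PairedSeries:
    """Apply a named strictly increasing map componentwise.

    Rank statistics (and hence every test result) are invariant under these
    maps; they only change the marginal distributions.
    """
    try:
        fn = MONOTONE_MAPS[name]
    except KeyError:
        raise ValueError(f"unknown monotone map {name!r}; available: {sorted(MONOTONE_MAPS)}")
    return PairedSeries(fn(p.x), fn(p.y))
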