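"""Kernel-weighted long-run variance of the rank cross-correlation estimators.

When both series are serially dependent, the asymptotic variance of
``sqrt(n) * rho_hat_S`` under pairwise independence inflates from 1 to

    sigma^2 = 1 + 2 * sum_{h>0} rho_SX(h) * rho_SY(h),

the sum running over the product of the lagged Spearman autocorrelations of the
two components.  The plug-in estimator truncates and downweights the sample
autocorrelations with a kernel ``kappa`` and bandwidth ``b_n``:

    sigma_hat^2 = 1 + 2 * sum_{h=1}^{n-2} kappa(h / b_n) rho_hat_SX(h) rho_hat_SY(h).

Defaults are the quartic kernel ``(1 - t^2)^2`` on [-1, 1] and ``b_n = 3 n^{1/4}``,
which satisfy the consistency conditions for short-range dependent (beta-mixing)
processes.  The bandwidth enters as a real number; no rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .rank_stats import PairedSeries, _check_not_constant, compute_ranks

__all__ = [
    "KernelSpec",
    "BandwidthRule",
    "LongRunVariance",
    "SigmaFloorWarning",
    "quartic_kernel",
    "bartlett_kernel",
    "default_bandwidth",
    "longrun_variance_from_autocorrs",
    "longrun_variance_estimate",
]


class SigmaFloorWarning(UserWarning):
    """The long-run variance estimate was non-positive and floored at 1/n."""


def quartic_kernel(t: float) -> float:
    """Quartic kernel: (1 - t^2)^2 on [-1, 1], zero outside."""
    t = float(t)
    if abs(t) > 1.0:
        return 0.0
    return (1.0 - t * t) ** 2


def bartlett_kernel(t: float) -> float:
    """Bartlett (triangular) kernel: 1 - |t| on [-1, 1], zero outside."""
    t = float(t)
    if abs(t) > 1.0:
        return 0.0
    return 1.0 - abs(t)


def default_bandwidth(n: int) -> float:
    """Default bandwidth rule b_n = 3 * n^(1/4) (not rounded)."""
    n = int(n)
    if n < 3:
        raise ValueError(f"need n >= 3 for a bandwidth, got {n}")
    return 3.0 * n ** 0.25


@dataclass(frozen=True)
class KernelSpec:
    """A lag-window kernel: symmetric, kappa(0)=1, |kappa|<=1, support [-1,1].

    The two built-ins are known to satisfy the regularity conditions required
    for consistency; a custom kernel is validated only against these finite
    properties — checking the full asymptotic assumption is the caller's
    responsibility.
    """

    name: str
    fn: Callable[[float], float]

    @classmethod
    def quartic(cls) -> "KernelSpec":
        return cls("quartic", quartic_kernel)

    @classmethod
    def bartlett(cls) -> "KernelSpec":
        return cls("bartlett", bartlett_kernel)

    @classmethod
    def from_name(cls, name: str) -> "KernelSpec":
        try:
            return {"quartic": cls.quartic, "bartlett": cls.bartlett}[name]()
        except KeyError:
            raise ValueError(f"unknown kernel {name!r}; choose 'quartic' or 'bartlett'")

    @classmethod
    def custom(cls, name: str, fn: Callable[[float], float]) -> "KernelSpec":
        spec = cls(name, fn)
        spec.validate()
        return spec

    def validate(self) -> None:
        if not np.isclose(self.fn(0.0), 1.0):
            raise ValueError("kernel must satisfy kappa(0) = 1")
        probe = np.linspace(0.0, 1.0, 21)
        for t in probe:
            a, b = self.fn(float(t)), self.fn(float(-t))
            if not np.isclose(a, b):
                raise ValueError(f"kernel not symmetric at t={t}")
            if abs(a) > 1.0 + 1e-12:
                raise ValueError(f"|kappa({t})| > 1")
        for t in (1.0 + 1e-9, 1.5, 10.0):
            if self.fn(t) != 0.0 or self.fn(-t) != 0.0:
                raise ValueError("kernel must vanish outside [-1, 1]")


@dataclass(frozen=True)
class BandwidthRule:
    """Bandwidth choice: the default rule 3 n^{1/4} or a fixed positive value."""

    kind: str = "default"  # "default" | "fixed"
    value: float | None = None

    def __post_init__(self):
        if self.kind not in ("default", "fixed"):
            raise ValueError(f"bandwidth kind must be 'default' or 'fixed', got {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None or not self.value > 0:
                raise ValueError("fixed bandwidth requires a positive value")

    @classmethod
    def auto(cls) -> "BandwidthRule":
        return cls("default")

    @classmethod
    def fixed(cls, value: float) -> "BandwidthRule":
        return cls("fixed", float(value))

    def resolve(self, n: int) -> float:
        if self.kind == "fixed":
            return float(self.value)
        return default_bandwidth(n)


@dataclass(frozen=True)
class LongRunVariance:
    """sigma_hat^2 with its per-lag contributions and estimator metadata."""

    sigma2: float
    contributions: Mapping[int, float]  # lag h -> kappa(h/bn) * ax(h) * ay(h)
    kernel: KernelSpec
    bandwidth: float
    floored: bool = False

    @property
    def raw_sigma2(self) -> float:
        """1 + 2 * sum of contributions, before the positivity floor."""
        return 1.0 + 2.0 * sum(self.contributions.values())


def longrun_variance_from_autocorrs(
    ax: np.ndarray,
    ay: np.ndarray,
    kernel: KernelSpec,
    bandwidth: float,
    n: int,
) -> LongRunVariance:
    """Assemble sigma_hat^2 from lagged rank autocorrelations (lags 1, 2, ...).

    ``ax[h-1]`` and ``ay[h-1]`` hold the lag-``h`` Spearman autocorrelations of
    the two components.  Applies the 1/n positivity floor.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    if ax.shape != ay.shape:
        raise ValueError("autocorrelation sequences must have equal length")
    contributions: dict[int, float] = {}
    for idx in range(ax.size):
        h = idx + 1
        w = kernel.fn(h / bandwidth)
        if w != 0.0:
            contributions[h] = w * ax[idx] * ay[idx]
    sigma2 = 1.0 + 2.0 * sum(contributions.values())
    floored = False
    if sigma2 <= 0.0:
        sigma2 = 1.0 / n
        floored = True
        warnings.warn(
            f"long-run variance estimate non-positive; floored at 1/n = {sigma2:.4g}",
            SigmaFloorWarning,
            stacklevel=2,
        )
    return LongRunVariance(
        sigma2=float(sigma2),
        contributions=contributions,
        kernel=kernel,
        bandwidth=float(bandwidth),
        floored=floored,
    )


def longrun_variance_estimate(
    p: PairedSeries,
    kernel: KernelSpec | None = None,
    bandwidth: BandwidthRule | None = None,
) -> LongRunVariance:
    """Estimate sigma^2 from a paired sample.

    Sums lags ``h = 1 .. n-2``; for compact-support kernels lags beyond the
    bandwidth contribute nothing and are skipped.
    """
    kernel = kernel or KernelSpec.quartic()
    bandwidth = bandwidth or BandwidthRule.auto()
    n = p.n
    if n < 4:
        raise ValueError(f"need n >= 4 for a long-run variance estimate, got {n}")
    bn = bandwidth.resolve(n)

    rx = compute_ranks(p.x)
    ry = compute_ranks(p.y)
    _check_not_constant(rx, "x")
    _check_not_constant(ry, "y")
    cx, cy = rx.centered(), ry.centered()
    ssx, ssy = rx.sum_sq(), ry.sum_sq()

    max_lag = n - 2
    lags = np.arange(1, max_lag + 1)
    weights = np.array([kernel.fn(h / bn) for h in lags])
    keep = weights != 0.0
    ax = np.zeros(max_lag)
    ay = np.zeros(max_lag)
    for idx in np.flatnonzero(keep):
        h = idx + 1
        ax[idx] = (cx[: n - h] @ cx[h:]) / ssx
        ay[idx] = (cy[: n - h] @ cy[h:]) / ssy
    return longrun_variance_from_autocorrs(ax, ay, kernel, bn, n)
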