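"""Rank-based point estimators of cross-correlation and serial correlation.

Spearman's Rho is the Pearson correlation of the rank vectors; Kendall's Tau is
the normalized count of concordant minus discordant pairs.  Both depend only on
the copula of the pair and are invariant under strictly increasing marginal
transforms.  The lagged Spearman autocorrelation defined here uses the
full-sample rank sum of squares in the denominator, the normalization that makes
the implied autocorrelation matrix positive semidefinite — a property the
long-run variance estimator relies on.

Ties are resolved by midranks with a warning: the asymptotic theory behind the
significance tests assumes absolutely continuous marginals, under which ties
have probability zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PairedSeries",
    "Ranks",
    "CorrelationEstimate",
    "DegenerateSeriesError",
    "TiesWarning",
    "compute_ranks",
    "spearman_rho_hat",
    "kendall_tau_hat",
    "spearman_autocorr",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series is constant (zero rank variance)."""


class TiesWarning(UserWarning):
    """Ties present: midranks are used, but the asymptotics assume no ties."""


def _as_finite_array(v, name: str = "series") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at index {bad}")
    return arr


@dataclass(frozen=True)
class PairedSeries:
    """Two aligned real-valued series of common length ``n``.

    The unit of testing: each index ``i`` pairs ``x[i]`` with ``y[i]``.
    Missing values are rejected outright — dropping pairs would silently
    destroy the serial structure the tests account for.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = _as_finite_array(self.x, "x")
        y = _as_finite_array(self.y, "y")
        if x.size != y.size:
            raise ValueError(f"length mismatch: len(x)={x.size}, len(y)={y.size}")
        if x.size < 3:
            raise ValueError(f"need at least 3 paired observations, got {x.size}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def lagged(self, lag: int) -> "PairedSeries":
        """Overlap after shifting ``y`` forward by ``lag`` relative to ``x``.

        Positive ``lag`` pairs ``x[i]`` with ``y[i+lag]``; negative pairs
        ``x[i+|lag|]`` with ``y[i]``.  The overlap has length ``n - |lag|``.
        """
        lag = int(lag)
        if lag == 0:
            return self
        if abs(lag) > self.n - 3:
            raise ValueError(f"|lag|={abs(lag)} leaves an overlap shorter than 3")
        if lag > 0:
            return PairedSeries(self.x[: self.n - lag], self.y[lag:])
        return PairedSeries(self.x[-lag:], self.y[: self.n + lag])


@dataclass(frozen=True)
class Ranks:
    """Rank vector with midrank tie handling.

    ``r`` sums to ``n(n+1)/2`` even with midranks; without ties it is a
    permutation of ``1..n`` and ``mean_rank == (n+1)/2``.
    """

    r: np.ndarray
    mean_rank: float
    tie_flag: bool

    @property
    def n(self) -> int:
        return self.r.size

    def centered(self) -> np.ndarray:
        return self.r - self.mean_rank

    def sum_sq(self) -> float:
        """Full-sample rank sum of squares, sum((R_i - Rbar)^2)."""
        c = self.centered()
        return float(c @ c)


@dataclass(frozen=True)
class CorrelationEstimate:
    measure: str  # "spearman" | "kendall"
    value: float
    lag: int = 0
    n_effective: int = 0

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"correlation estimate {self.value} outside [-1, 1]")


def compute_ranks(v, *, warn_ties: bool = True) -> Ranks:
    """Ascending ranks of ``v`` (rank 1 = smallest), midranks for ties."""
    arr = _as_finite_array(v)
    r = rankdata(arr, method="average")
    tie_flag = np.unique(arr).size < arr.size
    if tie_flag and warn_ties:
        warnings.warn(
            "ties present; midranks used, but the test's asymptotics assume "
            "continuous (tie-free) data",
            TiesWarning,
            stacklevel=2,
        )
    return Ranks(r=r, mean_rank=(arr.size + 1) / 2.0, tie_flag=tie_flag)


def _check_not_constant(ranks: Ranks, name: str) -> None:
    if ranks.sum_sq() == 0.0:
        raise DegenerateSeriesError(f"{name} is constant: rank variance is zero")


def spearman_rho_hat(p: PairedSeries, lag: int = 0) -> CorrelationEstimate:
    """Spearman's Rho: the Pearson correlation of the two rank vectors.

    With a nonzero ``lag`` the estimator is computed on the overlap (ranks are
    recomputed within the overlap).  For tie-free data it equals
    ``1 - 6 sum(d^2) / (m (m^2 - 1))`` with ``m`` the overlap length.
    """
    q = p.lagged(lag)
    rx = compute_ranks(q.x)
    ry = compute_ranks(q.y)
    _check_not_constant(rx, "x")
    _check_not_constant(ry, "y")
    cx, cy = rx.centered(), ry.centered()
    value = float(cx @ cy / np.sqrt((cx @ cx) * (cy @ cy)))
    value = float(np.clip(value, -1.0, 1.0))
    return CorrelationEstimate("spearman", value, lag=int(lag), n_effective=q.n)


def _merge_count(y: np.ndarray) -> int:
    """Exchange count of a bottom-up merge sort (number of inversions)."""
    y = y.copy()
    n = y.size
    buf = np.empty_like(y)
    swaps = 0
    width = 1
    while width < n:
        for lo in range(0, n - width, 2 * width):
            mid = lo + width
            hi = min(lo + 2 * width, n)
            i, j, k = lo, mid, lo
            while i < mid and j < hi:
                if y[i] <= y[j]:
                    buf[k] = y[i]
                    i += 1
                else:
                    buf[k] = y[j]
                    swaps += mid - i
                    j += 1
                k += 1
            buf[k:hi] = y[i:mid] if i < mid else y[j:hi]
            y[lo:hi] = buf[lo:hi]
        width *= 2
    return swaps


def _tie_pair_count(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def kendall_tau_hat(p: PairedSeries, lag: int = 0) -> CorrelationEstimate:
    """Kendall's Tau via Knight's O(m log m) algorithm.

    Computes ``(2 / (m (m - 1))) * sum_{i<j} sgn(x_j - x_i) sgn(y_j - y_i)``
    on the lag overlap.  Pairs tied in either coordinate contribute zero to the
    numerator while the denominator stays ``m (m - 1)`` (the tau-a convention,
    which the tie-free theory reduces to).
    """
    q = p.lagged(lag)
    rx = compute_ranks(q.x)
    ry = compute_ranks(q.y)
    _check_not_constant(rx, "x")
    _check_not_constant(ry, "y")
    m = q.n
    # Sort by x then y; discordant pairs among x-untied pairs are inversions in y.
    order = np.lexsort((q.y, q.x))
    ys = q.y[order]
    swaps = _merge_count(ys)
    n0 = m * (m - 1) // 2
    n1 = _tie_pair_count(q.x)
    n2 = _tie_pair_count(q.y)
    n3 = _tie_pair_count(np.rec.fromarrays([q.x, q.y]))
    # P - Q (concordant minus discordant); ties in either coordinate drop out.
    num = n0 - n1 - n2 + n3 - 2 * swaps
    value = 2.0 * num / (m * (m - 1))
    return CorrelationEstimate("kendall", float(value), lag=int(lag), n_effective=m)


def spearman_autocorr(v, h: int) -> float:
    """Lagged Spearman autocorrelation of a single series at lag ``h``.

    Numerator ``sum_{i=1}^{n-h} (R_i - Rbar)(R_{i+h} - Rbar)``, denominator the
    full-sample rank sum of squares.  Valid for ``1 <= h <= n - 2``; the
    full-sample denominator guarantees the lag-indexed correlation matrix is
    positive semidefinite.
    """
    arr = _as_finite_array(v)
    n = arr.size
    h = int(h)
    if not 1 <= h <= n - 2:
        raise ValueError(f"lag h={h} outside the admissible range [1, {n - 2}]")
    ranks = compute_ranks(arr)
    _check_not_constant(ranks, "series")
    c = ranks.centered()
    return float((c[: n - h] @ c[h:]) / ranks.sum_sq())
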