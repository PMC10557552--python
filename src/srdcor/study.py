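"""Monte-Carlo harness for type-I-error and power studies.

A study is a factorial grid over model parameters, sample sizes, methods and
measures.  Every cell gets its own deterministic random substream derived from
the root seed and the cell's position in the grid, so results do not depend on
execution order and a study is reproducible from (grid, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._batch import batch_simulate_var1, batch_simulate_vma, batch_spearman_test
from .longrun import BandwidthRule, KernelSpec
from .rank_stats import PairedSeries
from .simulate import VAR1Config, VMAConfig
from .testing import TestConfig, rank_cross_correlation_test

__all__ = ["StudyGrid", "StudyResult", "run_rejection_study", "power_curve", "summarize_study"]


@dataclass(frozen=True)
class StudyGrid:
    """Factorial simulation design.

    For ``model='var1'`` the autocorrelation axis is ``params`` = list of phi
    values (applied to both components, phi_x = phi_y); for ``model='vma'`` it
    is the list of half-window orders q.  ``rhos`` are cross-dependence values
    (0 for a type-I-error study), ``ns`` the sample sizes.
    """

    model: str = "var1"
    params: Sequence[float] = (0.0, 0.4, 0.8)
    rhos: Sequence[float] = (0.0,)
    ns: Sequence[int] = (40, 200)
    reps: int = 10_000
    alpha: float = 0.05
    methods: Sequence[str] = ("classical", "modified")
    measures: Sequence[str] = ("spearman",)
    nu: float = 4.0
    kernel: KernelSpec = field(default_factory=KernelSpec.quartic)
    bandwidth: BandwidthRule = field(default_factory=BandwidthRule.auto)
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("var1", "vma"):
            raise ValueError(f"model must be 'var1' or 'vma', got {self.model!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.methods:
            raise ValueError("at least one method is required")
        if not self.measures:
            raise ValueError("at least one measure is required")
        for m in self.methods:
            if m not in ("classical", "modified"):
                raise ValueError(f"unknown method {m!r}")
        for m in self.measures:
            if m not in ("spearman", "kendall"):
                raise ValueError(f"unknown measure {m!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def cells(self):
        idx = 0
        for param in self.params:
            for rho in self.rhos:
                for n in self.ns:
                    yield idx, param, rho, n
                    idx += 1


@dataclass(frozen=True)
class StudyResult:
    """Tidy rejection-rate table, one row per (cell, method, measure)."""

    table: pd.DataFrame
    grid: StudyGrid

    COLUMNS = (
        "model",
        "param",
        "rho",
        "n",
        "method",
        "measure",
        "rejection_rate",
        "mc_se",
        "reps",
    )


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,)))


def _simulate_cell(grid: StudyGrid, param: float, rho: float, n: int, rng):
    if grid.model == "var1":
        cfg = VAR1Config(phi_x=param, phi_y=param, rho=rho, n=n)
        return batch_simulate_var1(cfg, grid.reps, rng)
    q = int(param)
    cfg = VMAConfig(q=q, nu=grid.nu, rho=rho, n=n, independent_t=(rho == 0.0))
    return batch_simulate_vma(cfg, grid.reps, rng)


def _kendall_rejections(x, y, method, grid) -> np.ndarray:
    cfg = TestConfig(
        measure="kendall", method=method, alpha=grid.alpha, kernel=grid.kernel, bandwidth=grid.bandwidth
    )
    out = np.empty(x.shape[0], dtype=bool)
    for i in range(x.shape[0]):
        out[i] = rank_cross_correlation_test(PairedSeries(x[i], y[i]), cfg).reject
    return out


def run_rejection_study(grid: StudyGrid) -> StudyResult:
    """Run the full grid and tabulate rejection frequencies with MC standard errors.

    Under rho = 0 rows report the observed type-I error; under rho != 0 the
    observed power.  Deterministic given ``grid.seed``.
    """
    rows = []
    for cell_index, param, rho, n in grid.cells():
        rng = _cell_rng(grid.seed, cell_index)
        x, y = _simulate_cell(grid, param, rho, n, rng)
        for measure in grid.measures:
            for method in grid.methods:
                if measure == "spearman":
                    _, _, rej = batch_spearman_test(
                        x, y, method, grid.alpha, grid.kernel, grid.bandwidth
                    )
                else:
                    rej = _kendall_rejections(x, y, method, grid)
                rate = float(np.mean(rej))
                rows.append(
                    {
                        "model": grid.model,
                        "param": param,
                        "rho": rho,
                        "n": n,
                        "method": method,
                        "measure": measure,
                        "rejection_rate": rate,
                        "mc_se": float(np.sqrt(rate * (1.0 - rate) / grid.reps)),
                        "reps": grid.reps,
                    }
                )
    table = pd.DataFrame(rows, columns=list(StudyResult.COLUMNS))
    return StudyResult(table=table, grid=grid)


def power_curve(grid: StudyGrid) -> StudyResult:
    """Rejection study under the alternative, ordered by sample size for plotting."""
    if all(r == 0.0 for r in grid.rhos):
        raise ValueError("a power study needs at least one rho != 0")
    grid = replace(grid, rhos=tuple(r for r in grid.rhos if r != 0.0))
    result = run_rejection_study(grid)
    table = result.table.sort_values(["param", "rho", "method", "n"], kind="stable").reset_index(drop=True)
    return StudyResult(table=table, grid=grid)


def summarize_study(result: StudyResult, path, fmt: str = "csv") -> None:
    """Write the tidy result table to CSV or JSON with a stable column order."""
    if result.table.empty:
        raise ValueError("empty study result")
    if fmt == "csv":
        result.table.to_csv(path, index=False)
    elif fmt == "json":
        result.table.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}; choose 'csv' or 'json'")
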