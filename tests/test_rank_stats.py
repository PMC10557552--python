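"""Rank computation and the Spearman/Kendall point estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau, spearmanr

from srdcor import (
    DegenerateSeriesError,
    PairedSeries,
    compute_ranks,
    kendall_tau_hat,
    spearman_autocorr,
    spearman_rho_hat,
)
from srdcor.rank_stats import TiesWarning


def kendall_pair_oracle(x, y):
    """O(n^2) sign-pair enumeration: the defining formula of tau."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    return 2.0 * s / (n * (n - 1))


def spearman_d2_oracle(x, y):
    """1 - 6 sum(d^2)/(n(n^2-1)) — valid for tie-free data only."""
    rx = compute_ranks(x).r
    ry = compute_ranks(y).r
    n = len(rx)
    return 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n * n - 1))


finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)
unique_series = st.lists(finite_floats, min_size=4, max_size=50, unique=True)


class TestComputeRanks:
    @pytest.mark.parametrize(
        "v, expected, tie_flag",
        [
            ([3.1, 1.2, 2.7], [3, 1, 2], False),
            ([1, 1, 2], [1.5, 1.5, 3], True),
            (list(range(1, 8)), list(range(1, 8)), False),
        ],
    )
    def test_examples(self, v, expected, tie_flag):
        r = compute_ranks(v, warn_ties=False)
        assert r.r.tolist() == expected
        assert r.tie_flag is tie_flag

    def test_ties_warn(self):
        with pytest.warns(TiesWarning):
            compute_ranks([1.0, 1.0, 2.0])

    @given(v=st.lists(finite_floats, min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_rank_sum_invariant(self, v):
        r = compute_ranks(v, warn_ties=False)
        n = len(v)
        assert r.r.sum() == pytest.approx(n * (n + 1) / 2)
        if not r.tie_flag:
            assert sorted(r.r.tolist()) == list(range(1, n + 1))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            compute_ranks([1.0, np.nan, 2.0])


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        assert spearman_rho_hat(PairedSeries(x, x * 3 + 1)).value == pytest.approx(1.0)
        assert spearman_rho_hat(PairedSeries(x, -x)).value == pytest.approx(-1.0)

    def test_small_example(self):
        p = PairedSeries([1, 2, 3, 4], [1, 3, 2, 4])
        assert spearman_rho_hat(p).value == pytest.approx(0.8)

    @given(
        x=unique_series,
        y=unique_series,
    )
    @settings(max_examples=100, derandomize=True)
    def test_equals_pearson_on_ranks_and_d2(self, x, y):
        m = min(len(x), len(y))
        x, y = x[:m], y[:m]
        p = PairedSeries(x, y)
        rho = spearman_rho_hat(p).value
        rx = compute_ranks(x).r
        ry = compute_ranks(y).r
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        assert rho == pytest.approx(spearman_d2_oracle(x, y), abs=1e-12)

    def test_matches_scipy(self, iid_pair):
        assert spearman_rho_hat(iid_pair).value == pytest.approx(
            spearmanr(iid_pair.x, iid_pair.y).statistic
        )

    def test_constant_series_error(self):
        with pytest.raises(DegenerateSeriesError):
            spearman_rho_hat(PairedSeries([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestKendall:
    def test_trivial_cases(self):
        x = np.arange(8.0)
        assert kendall_tau_hat(PairedSeries(x, np.exp(x))).value == pytest.approx(1.0)
        assert kendall_tau_hat(PairedSeries(x, -x)).value == pytest.approx(-1.0)

    def test_small_example(self):
        assert kendall_tau_hat(PairedSeries([1, 2, 3], [1, 3, 2])).value == pytest.approx(1 / 3)

    @given(
        x=st.lists(st.integers(-8, 8), min_size=4, max_size=60),
        y=st.lists(st.integers(-8, 8), min_size=4, max_size=60),
    )
    @settings(max_examples=150, derandomize=True)
    def test_mergesort_equals_pair_oracle_with_ties(self, x, y):
        m = min(len(x), len(y))
        x, y = np.array(x[:m], float), np.array(y[:m], float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        tau = kendall_tau_hat(PairedSeries(x, y)).value
        assert tau == pytest.approx(kendall_pair_oracle(x, y), abs=1e-12)

    def test_matches_scipy_on_tiefree(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        tau = kendall_tau_hat(PairedSeries(x, y)).value
        assert tau == pytest.approx(kendalltau(x, y).statistic, abs=1e-12)
        assert tau == pytest.approx(kendall_pair_oracle(x, y), abs=1e-12)


class TestMonotoneInvariance:
    @pytest.mark.parametrize("fn", [np.exp, lambda v: v**3, lambda v: 2.0 * v - 5.0])
    def test_both_estimators_invariant(self, iid_pair, fn):
        q = PairedSeries(fn(iid_pair.x), fn(iid_pair.y))
        assert spearman_rho_hat(q).value == pytest.approx(spearman_rho_hat(iid_pair).value)
        assert kendall_tau_hat(q).value == pytest.approx(kendall_tau_hat(iid_pair).value)


class TestLaggedEstimation:
    def test_positive_lag_pairs_x_with_future_y(self, rng):
        # Construct y so that y[i+2] is a monotone image of x[i]: at lag=+2 the
        # overlap is perfectly concordant even though at lag 0 it is not.
        x = rng.normal(size=40)
        y = np.empty(40)
        y[2:] = np.exp(x[:-2])
        y[:2] = rng.normal(size=2)
        p = PairedSeries(x, y)
        lagged = spearman_rho_hat(p, lag=2)
        assert lagged.n_effective == 38
        assert lagged.value == pytest.approx(1.0)
        assert abs(spearman_rho_hat(p, lag=0).value) < 0.5

    def test_negative_lag_mirrors_positive(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = spearman_rho_hat(PairedSeries(x, y), lag=-4)
        b = spearman_rho_hat(PairedSeries(y, x), lag=4)
        assert a.value == pytest.approx(b.value)
        assert a.n_effective == b.n_effective == 26

    def test_lag_too_large(self):
        p = PairedSeries(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            spearman_rho_hat(p, lag=8)


class TestSpearmanAutocorr:
    def test_increasing_series_lag1(self):
        assert spearman_autocorr(np.arange(5.0) * 2 + 1, 1) == pytest.approx(0.4)

    def test_iid_near_zero(self, rng):
        v = rng.standard_normal(2000)
        assert abs(spearman_autocorr(v, 1)) < 3 / np.sqrt(2000)

    def test_lag_bounds(self):
        v = np.arange(10.0)
        with pytest.raises(ValueError):
            spearman_autocorr(v, 0)
        with pytest.raises(ValueError):
            spearman_autocorr(v, 9)

    def test_autocorr_matrix_psd(self, rng):
        for _ in range(5):
            v = rng.standard_normal(40).cumsum()  # strongly dependent path
            n = len(v)
            acs = [1.0] + [spearman_autocorr(v, h) for h in range(1, n - 1)]
            mat = np.array([[acs[abs(i - j)] for j in range(n - 1)] for i in range(n - 1)])
            eig = np.linalg.eigvalsh(mat)
            assert eig.min() > -1e-8

    def test_values_within_unit_interval(self, rng):
        v = rng.standard_normal(50)
        for h in (1, 5, 20):
            assert -1.0 <= spearman_autocorr(v, h) <= 1.0
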