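# Methods

## Model and estimands

Let (X_i, Y_i) be a strictly stationary bivariate process whose components are
individually serially dependent but — under the null hypothesis — mutually
independent. Dependence is quantified by Spearman's Rho, the Pearson
correlation of the rank vectors,

    ρ̂_S = Σ (R_i^X − R̄^X)(R_i^Y − R̄^Y) / √(Σ (R_i^X − R̄^X)² Σ (R_i^Y − R̄^Y)²),

and Kendall's Tau, τ̂ = 2 Σ_{i<j} sgn(R_j^X − R_i^X) sgn(R_j^Y − R_i^Y) / (n(n−1)).
Both depend only on the copula and are invariant under strictly increasing
marginal transforms; the package asserts this invariance as a property test.

Under absolute regularity (β-mixing) with summable coefficients and continuous
marginals, √n ρ̂_S is asymptotically N(0, σ²) with

    σ² = 1 + 2 Σ_{h>0} ρ_SX(h) ρ_SY(h),

and √n τ̂ is asymptotically N(0, (4/9) σ²) — the same inflation factor for
both measures. σ² exceeds 1 exactly when both components are autocorrelated
with like signs; if at most one component is serially dependent, σ² = 1 and
the classical iid result is recovered. β-mixing is an assumption, not a
quantity estimated from data: the test is valid for the wide class of
short-range dependent processes (stationary ARMA, many GARCH, transformed
Gaussian processes, M-dependent processes) but not for long-range dependence.

## Long-run variance estimator

σ² is estimated by a kernel lag window over sample Spearman autocorrelations:

    σ̂² = 1 + 2 Σ_{h=1}^{n−2} κ(h/bₙ) ρ̂_SX(h) ρ̂_SY(h),
    ρ̂_SX(h) = Σ_{i=1}^{n−h} (R_i^X − R̄^X)(R_{i+h}^X − R̄^X) / Σ_{i=1}^{n} (R_i^X − R̄^X)².

Numerical choices, with rationale:

* **Denominator of ρ̂_SX(h).** The full-sample rank sum of squares (not a
  lag-dependent or two-segment normalization). This is the standard
  autocorrelation normalization whose lag-indexed correlation matrix is
  positive semidefinite — verified by a property test — and it matches what
  `acf`-style estimators compute.
* **Kernel.** Default quartic, κ(t) = (1 − t²)² on [−1, 1]; Bartlett is
  built in; custom kernels are accepted but validated only against the finite
  requirements (κ(0)=1, symmetry, |κ|≤1, compact support). The asymptotic
  regularity of a user-supplied kernel/bandwidth pair is the user's
  responsibility — it is a rate condition not checkable from a single n.
* **Bandwidth.** bₙ = 3 n^{1/4}, kept as a real number (no truncation to an
  integer). Lags with κ(h/bₙ) = 0 are skipped. No data-adaptive bandwidth
  selection is offered; doubling the bandwidth gives a more conservative test
  at a power cost (asserted as a study-harness test).
* **Positivity floor.** σ̂² can be non-positive in pathological small samples
  (strong negative autocorrelation products); it is floored at 1/n with a
  `floored` flag and a warning. The floor vanishes asymptotically and keeps
  the statistic defined.
* **Ties.** The asymptotics assume continuous marginals, so ties occur with
  probability zero in the intended applications. Observed ties get midranks
  and a `TiesWarning`; only a constant series is a hard error.
* **Missing values.** Rejected, never pairwise-deleted: deletion would
  silently change the serial structure that σ̂² estimates.

## Test statistics

    T_ρ = √n ρ̂_S / √σ̂²,      T_τ = √n τ̂ / √((4/9) σ̂²),

compared against the standard normal (no continuity correction). The
**classical** comparator substitutes σ̂² = n/(n−1); for Kendall the same
substitution is used by default (the two classical variants differ only at
O(1/n)), with an `exact_iid_kendall` option using the textbook null variance
2(2n+5)/(9n(n−1)) for cross-checking. One-sided alternatives are available
although the studies use two-sided tests. With a lag k, the pair
(x_i, y_{i+k}) is tested on the overlap of length n−|k|, which replaces n
everywhere (estimate, σ̂², √n). Kendall's Tau is computed with Knight's
O(n log n) merge-sort algorithm, pinned by tests to agree exactly with the
O(n²) sign-pair enumeration.

## Simulators

* **Model 1 — VAR(1).** Diagonal AR matrix (φ_X, φ_Y), Gaussian innovations
  with unit variances and correlation ρ. Initialization is an exact draw from
  the stationary law (variances 1/(1−φ²), cross-covariance ρ/(1−φ_X φ_Y)), so
  paths are strictly stationary from the first observation; a burn-in option
  exists only for cross-checking. With φ_X = φ_Y the parameter ρ is also the
  stationary Pearson cross-correlation, and the population Spearman
  cross-correlation is (6/π) asin(ρ/2) — used as a ground-truth oracle.
* **Model 2 — vector moving average.** Equal weights 1/(2q+1) over 2q+1
  consecutive bivariate-t innovations (elliptical construction Z√(ν/W),
  W ~ χ²_ν; default ν = 4). n + 2q innovations are drawn so the output length
  is exactly n with no edge truncation. For null (ρ = 0) studies the harness
  draws two *independent* univariate t innovations, since the elliptical
  ρ = 0 case is uncorrelated but not independent. q = 0 is an iid process.

Reproducibility: each simulator accepts a seed; the study harness derives one
deterministic substream per grid cell from the root seed via
`SeedSequence(seed, spawn_key=(cell,))`, so results are independent of
execution order.

## Monte-Carlo harness and problem sizes

The harness evaluates rejection frequencies over factorial grids
(model parameter × ρ × n × method × measure) and reports each cell with its
binomial standard error √(r(1−r)/reps). Spearman cells run through a
vectorized replicate engine (rank, correlate and kernel-sum whole
(reps × n) matrices); the engine is pinned by tests to agree with the scalar
API to 1e-12, so vectorization adds speed, not a second definition. The
headline null experiment (φ = 0.8, n = 50) uses the full 10,000 replicates;
qualitative grid properties (monotone inflation in φ and q, classical power ≥
modified power under autocorrelation, power → 1 for ρ ≥ 0.7 by n = 500,
near-zero iid power gap) are asserted at 1,000 replicates per cell, and
distributional sanity checks (σ̂² → 1 for iid pairs, ground-truth recovery of
(6/π) asin(ρ/2)) at a few hundred replicates of long paths — sizes chosen so
each Monte-Carlo tolerance (3× its standard error, with small absolute slack)
is still discriminating.

## Smoothing pipeline

Annual paired station series are smoothed with a centered equal-weight moving
average (default window 5). Edge values whose windows would be incomplete are
**trimmed**, not shrunk, so the filter acts exactly like an equal-weight
moving average of independent annual values — the same mechanism as Model 2
with q = 2 — and the modified test's assumptions apply to the smoothed series.
Stations with missing years are rejected and logged, never interpolated.
Tests operate on smoothed raw values (smooth, then rank inside the test);
ranking before smoothing is a different operator, and a test asserts the
pipeline order. No multiplicity correction is applied across stations: the
per-station level is α, and the network-level summary counts significant
stations — users screening many stations may want to add their own FDR
control on the reported p-values.

The synthetic station network draws, per station, either independent annual
pairs or cross-dependent pairs (innovation correlation 0.6 by default) with
serially independent years (φ = 0), 51 years per station by default — the
length of a typical mid-century-to-2010 annual record. It emulates the shape
and the null structure of a real network, not its spatial correlation: real
neighbouring catchments share weather and are cross-station dependent, so
passing network tests here says nothing about field significance in spatial
data.

## Known limitations

* The modified test retains a small-sample type-I excess under strong
  bilateral autocorrelation: at φ_X = φ_Y = 0.8 and n = 50 the measured level
  at α = 0.05 is ≈ 0.086, because sample rank autocorrelations are biased
  toward zero at that n and the kernel truncates the autocorrelation tail, so
  σ̂² (mean ≈ 2.5) underestimates the finite-sample variance of √n ρ̂_S
  (≈ 3.5). The excess decays with n (≈ 0.068 at n = 200, asserted by a test)
  and is intrinsic to the estimator, not an implementation artifact — the
  implementation agrees to seven decimals with an independently hand-rolled
  rank/acf/kernel construction in R.
* Long-range dependent processes (e.g. fractional Gaussian noise) are outside
  the theory; the test gives no guarantees there.
* Confidence intervals for ρ_S or τ under dependence would need a long-run
  variance estimator valid under pairwise *dependence* and are not provided.
* The tie-handling (midranks) is a pragmatic convention; no ties-corrected
  asymptotic theory is implemented.
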