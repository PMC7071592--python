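# Methods

## Model and scope

All procedures assume one i.i.d. sample X₁,…,X_N from N(μ, σ²) with both
parameters unknown, N ≥ 2.  The estimand is a single percentile
θ = μ + z_p σ with fixed, user-chosen level p ∈ (0, 1).  Inference on
several percentiles jointly, non-normal data, and interval estimation as a
first-class output are out of scope (the two-sided test is, by duality,
equivalent to checking whether θ₀ lies in the exact confidence interval
obtained by inverting the pivot, and a property test asserts exactly
that).

## Exact procedures

The pivot T = (X̄ − θ)/(S/√N) has law t(ν, −z_p√N), ν = N − 1.  Writing
τ_q for the q-quantile of that distribution:

- difference (H₁: θ ≠ θ₀): reject when T₀ < τ_{α/2} or T₀ > τ_{1−α/2},
  with T₀ = (X̄ − θ₀)/(S/√N);
- noninferiority, larger-is-better (H₁: θ > θ₀): reject when T₀ > τ_{1−α};
  smaller-is-better mirrors with τ_α;
- equivalence (H₁: |θ − θ_T| < δ): two one-sided tests; reject when
  T_L = (X̄ − θ_T + δ)/(S/√N) > τ_{1−α} **and**
  T_U = (X̄ − θ_T − δ)/(S/√N) < τ_α.

Because the reference law is the true sampling law, the size is exactly α
(α/2 per tail two-sided).  The suite asserts this analytically to 1e−10
over a grid of (N, p, α).

## Approximate procedures

Chakraborti–Li standardizes θ̂_M = X̄ + z_p c S using
Var[θ̂_M] = m σ²/N, m = 1 + N z_p²(c² − 1); Bland–Altman standardizes
θ̂_B = X̄ + z_p S using b = 1 + z_p²/2.  Both treat the standardized
statistic as central t(ν) and reuse the classical two-sided / one-sided /
TOST rejection rules with t-quantiles.  Every such rule can be rewritten
on the pivotal scale: e.g. T_M0 > t is equivalent to
T > t√m − z_p c√N.  The implementation exploits this identity in one
place (`_power.pivotal_critical`), which makes the three methods a single
code path differing only in the critical value; the identity itself is
property-tested against the literal estimator-scale statistics.

At p = 0.5, z_p = 0 forces m = b = 1 and c z_p = 0, so all three methods
are literally the same test — statistics, decisions, powers and sample
sizes coincide, and the suite checks all four collapses.

## Power functions

With Δ = (μ − θ₀)√N/σ, the difference-test power is
P{t(ν,Δ) < C_{α/2}} + P{t(ν,Δ) > C_{1−α/2}}, where C_q is the
pivotal-scale critical value of the method in use (τ_q exactly;
t_q√m − z_p c√N or t_q√b − z_p√N for the approximations).  One-sided
powers keep the matching single term.  Two points where the printed
source equations needed care, both validated against Monte Carlo:

- the Bland–Altman two-sided power is implemented with its second term as
  an upper-tail probability (the lower/upper pair mirrors the
  Chakraborti–Li form); taking both terms as lower tails would not reduce
  to the size at the null;
- the chi-square threshold κ for the Chakraborti–Li equivalence
  expectation uses σ² in its denominator (dimensional analysis; the σ-only
  form is inconsistent with the exact and Bland–Altman analogues).

### Equivalence power: two forms

The TOST power has an exact representation as an expectation over
K = νS²/σ² ~ χ²(ν):  E_K[H·{Φ(U) − Φ(L)}], where H indicates
K < κ = 4νNδ²/{σ²(C_{1−α} − C_α)²}, the point where the two one-sided
acceptance bounds cross.  `tost_power_quadrature` evaluates it by
Gauss–Legendre quadrature (256 nodes, doubled for a convergence check at
1e−7 absolute; a failure raises a computation error with diagnostics) on
K ∈ (0, min(κ, q_{χ²}(1 − 1e−12))).

Because P{K ≥ κ} is numerically zero for all realistic designs, the
noncentral-t shortcut P{t(ν,Δ_U) < C_α} − P{t(ν,Δ_L) < C_{1−α}}
(clipped at 0) agrees with the expectation to well under 1e−4 and is the
default power used everywhere, including sample-size search.  The
quadrature form is exposed for verification and genuinely differs only in
pathological designs (N ≈ 3 with wide margins), where it is the
trustworthy one; a 10⁶-replicate simulation pins it there.

## Sample-size determination

`required_sample_size` scans N = 2, 3, … (vectorized in geometrically
growing blocks, default cap 10⁶) and returns the first N whose analytic
power reaches the target.  A scan rather than bisection because the power
is not guaranteed monotone in N at very small N for extreme p; the scan
makes minimality unconditional, and the bracketing property (power at
N−1 below target) is asserted for every returned result.  Ties go to the
smallest N.

## Monte Carlo engine

Each simulation cell draws all `reps` samples (default 10,000, matching
the benchmark study) as one (reps × N) block from a single
`numpy.random.Generator`, reduces each row to (mean, SD with divisor
N − 1) — the same reduction applied to user data — and applies the
rejection rule on the pivotal scale.  Tail-wise rates are reported with
binomial standard errors, and errors are rates minus nominal (α/2 per
tail, α overall).  `regenerate_table` spawns one child `SeedSequence` per
(table cell × method) from the root seed, so per-cell results are
independent of evaluation order.  A per-replicate stream design was considered and
rejected: it costs an order of magnitude in generator setup without
changing any statistical property at this scale.

Null configurations place the true percentile exactly on the null
boundary: θ₀ = μ₀ + z_p σ₀ for difference/noninferiority, and
μ = θ_T − δ − z_p σ₀ for equivalence (true θ at θ_T − δ).

The engine is the package's own oracle in both directions: analytic
powers are required to sit within 3 binomial SEs of 10⁵-replicate
simulations for every method × test type, and the exact method's
simulated errors must stay within 0.01 of nominal across the full
benchmark grid.

### What the simulations do and do not show

The generator draws exactly normal data, so passing calibration checks
demonstrate correctness of the distributional algebra, not robustness:
nothing here speaks to skewed or heavy-tailed populations, measurement
rounding, or dependence between observations.  One benchmark constant
deserves a note: the published lower-tail error excess 0.0201 for the
Chakraborti–Li difference test (p = 0.9, N = 39) is itself a single
10,000-replicate estimate; the analytic value of that excess is 0.0160
(confirmed here by 4×10⁶-replicate brute force), so seeded reproductions
scatter around 0.0160 with SE ≈ 0.002 and only statistically match the
printed draw.

## Numerical choices

- z_p and all internal constants are evaluated at full double precision;
  published 4-decimal constants appear only as test tolerances.
- c is computed as exp(log-gamma differences) times √(ν/2), stable to at
  least ν ~ 10⁶ (overflow-free where raw Γ ratios fail beyond ν ≈ 340).
- The noncentral t is accessed through a single wrapper pair
  (`nct_cdf`/`nct_sf`/`nct_quantile`).  ncp = 0 is routed to the central
  t.  The scipy evaluator returns NaN deep in the tails (true
  probabilities below ~1e−35 or within ~1e−16 of 1); the wrapper patches
  those with a Jennett–Welch normal approximation, whose absolute error
  is negligible precisely there.  The quantile/CDF round trip is enforced
  to 1e−8 over df ∈ [1, 200], |ncp| ≤ 20.
- SD = 0 input: the test statistic is ±∞ by the sign of its numerator
  (0 when the numerator is 0), with a warning rather than an error; the
  decision follows the usual comparison.
- p-values are an extension, not part of the published procedures: the
  reference distributions are asymmetric, so the two-sided value is the
  conventional 2·min(F, 1−F) of the method's own reference CDF, and the
  TOST value is max of the two one-sided values.  reject ⟺ p < α is
  property-tested.

## Known limitations

- Single-sample problems only; no two-group percentile comparisons.
- The approximate methods are provided for comparison, not recommended:
  their one-sided sizes drift from nominal for small N and |p − 0.5|
  large, which is exactly what the simulation engine demonstrates.
- Sample-size search assumes the analytic power forms; for equivalence at
  N ≤ 4 with large margins the noncentral-t shortcut can overstate power
  (see the quadrature discussion above), though no realistic design sits
  there.
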