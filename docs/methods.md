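# Methods

This note records the statistical model the package implements, the
conventions and numerical choices that were genuinely open, and what the
synthetic-data validation does and does not establish.

## Model and estimation chain

The system is a trivariate daily VAR on transformed scales. Counts `y` are
mapped through the inverse hyperbolic sine `g = ln(θy + √(1+θ²y²))`, `θ = 1`
by default, chosen over `log(y+1)` because it is exactly odd, strictly
increasing, behaves as `log(2y)` for large `y`, and needs no offset at zero —
the officer-death series is zero on ~88% of days. On this scale linear
coefficients read as approximate elasticities. The tweet-volume series is
IHS-transformed first and then first-differenced (transform-then-difference,
so the differenced variable is a growth rate); the two homicide series stay
in levels. Each series is screened with an ADF test (drift, augmentation lag
by BIC over 0–14, asymptotic 95% critical value −2.86) and a KPSS test
(Bartlett kernel, Schwert lag `⌊4(n/100)^{1/4}⌋`, critical value 0.463);
differencing is proposed only when the two tests agree the series is
integrated.

The reduced-form VAR(p) is estimated by equation-wise OLS (identical to
joint least squares for an unrestricted VAR), `p` chosen by AIC
(`ln det Σ̂ + 2k/T`) on a common estimation sample with rows starting at
`p_max`; a `pinned_lag` option bypasses selection for replication of a
fixed published order. Residual covariance for AIC divides by the effective
sample size (ML convention); the regime covariances below divide by the
per-regime row count without a df adjustment, which keeps the moment system
internally consistent.

## Regimes

Variance shifts in a series appear as mean shifts in its rolling standard
deviation, so regime dating runs on the 20-observation trailing rolling sd
of the differenced tweet series (daily stepped; a weekly convention would
discard resolution without changing the estimand). Multiple mean breaks are
fit by exact dynamic programming over all segmentations with a minimum
segment share of 15%, the break count `m ≤ 5` chosen by
`BIC = n ln(SSR/n) + (2m+1) ln n`. The DP is tested against exhaustive
enumeration on short fixtures. Because a trailing window smears a variance
step at day `b` over the following window, the fitted mean shift centres
near `b + w/2`; when a volatility break is mapped back to a panel date the
pipeline subtracts `w//2` days. Only the optimal *single*-break split feeds
identification (the moment system is written for two regimes); additional
BIC-preferred breaks are reported with a warning. The per-break confidence
band is the profile-SSR region under a 95% χ²(1) increment — an
approximation, labelled as such, since the exact break-date distribution is
nonstandard. Residual rows on or before the break date form regime 2 (low
volatility), later rows regime 1 (high volatility): regime 1 is the
turbulent period even though it comes later in time.

## Identification

With `B = A⁻¹` unit-diagonal, the two-regime moment system
`Σ_i = B diag(v_i) Bᵀ` (12 equations, 12 unknowns) is solved as a
root-finding problem in `(δ, log v₁, log v₂)` — the log parameterization
enforces positive variances — using Powell's hybrid method with an analytic
Jacobian. The system is polynomial and has multiple exact roots: any
relabeling of shocks that keeps the diagonal nonzero produces another root
with permuted, rescaled variances. The solver therefore multi-starts from
(a) the caller-supplied warm start if any, (b) δ = 0 with the covariance
diagonals, (c) triangular (Cholesky) factorizations of the pooled and
per-regime covariances under **all six variable orderings**, conjugated
back to the original order, and (d) randomized perturbations with
escalating scales. Among admissible roots (moment residual below 1e−8,
positive variances) it returns the smallest-‖δ‖ root: under the unit-diagonal
normalization this is the branch on which each shock loads primarily on its
own variable, which is the only economically meaningful labelling. The
convention is reliable when own-effects dominate (|δ| below ~1); for systems
with very large cross-effects the labelling is intrinsically ambiguous and
occasional relabeled solutions are possible — they are exact roots, not
numerical failures. Identification requires genuinely different regimes:
identical covariances raise an error (6 equations, 9 unknowns), and a guard
refuses to solve when all three residual variance ratios lie in [0.9, 1.1]
unless forced.

Two diagnostics validate the regime split: one-sided bootstrap tests that
each shock variance is larger in regime 1, and pairwise "uniqueness" tests
that the regime shift is not proportional across shocks (a proportional
shift carries no identifying information). Bootstrap p-values use the
(count+1)/(B+1) correction, so exact zeros are never reported.

## Wild bootstrap

Inference is a fixed-design wild bootstrap (default B = 500): one weight per
day multiplies the whole residual row, outcomes are rebuilt on the fixed
regressor matrix, coefficients refit, regime covariances recomputed at the
original break date, and the moment system re-solved warm-started at the
point solution. The break date is held fixed across replicates — inference
is conditional on the estimated regimes.

The weight law matters unusually much here. The identified parameters are
functions of second moments only, and any sign-flip law (Rademacher) leaves
`w_t² ê_t ê_tᵀ` unchanged, so it propagates *no* sampling variation into the
moment system: replicate deltas collapse onto the point estimate and
standard errors are understated by an order of magnitude. The default is
therefore Mammen's two-point law (`E w² = 1`, `Var w² = 1`), whose replicate
covariance variation slightly over-states Gaussian sampling variance
(factor ≈ 1.5 on fourth moments), giving mildly conservative intervals;
observed 95%-interval coverage for the officer→citizen coefficient on
synthetic panels is near nominal. Rademacher, Gaussian, and unit-weight laws
remain available (`weights=`), the last for exactness tests. Coefficient
p-values are symmetric-percentile: replicates centred at the point estimate,
doubled smaller tail share beyond |estimate|, with the +1 correction.

## Impulse responses and practical conversions

`Φ_h = Ψ_h B` with `Ψ_h` read off companion-matrix powers; `Φ_0 = B`
exactly. The differenced tweet row is reported cumulatively so it reads like
the level rows. A "1% shock" is a unit impulse on the IHS (log-like) scale,
so responses are percent-per-percent; bands are the point estimate ± 1 and
± 2 pointwise replicate standard deviations (the 2-sd band is the
conventional ≈95% reading), and a response is flagged significant where the
2-sd band excludes zero. Practical conversions multiply an elasticity by the
raw-count sample mean: a 100% shock to officer deaths with `δ₂₁ = 0.628` and
a citizen baseline of 1.238/day is an extra `0.628 × 1.238 ≈ 0.8` citizens
shot that day.

## Synthetic data: what it emulates, and what passing tests show

The generator simulates the latent transformed-scale VAR exactly (Gaussian
shocks by default; a scaled t(5) option stress-tests the bootstrap), with a
200-step burn-in in the pre-break regime, then inverts the IHS to integer
counts either by `max(0, round(sinh g))` (default, deterministic) or by
Poisson sampling. The default parameter point places the system in the
empirically estimated regime: contemporaneous coefficients
`(−0.0928, 1.2525, 0.6280, 0.8174, −0.2744, −0.0005)`, regime shock
variances `(0.0970, 0.3303, 0.0415)` post-break vs `(0.0582, 0.4317,
0.0118)` pre-break (tweet ratio ≈ 3.2), small stable lag matrices
(companion radius ≈ 0.3 — the estimated daily dynamics are weak), and
intercepts pinned so latent means match the observed transformed means
(0.1059, 0.8738, 0). The default break index 542 of 639 leaves 15.02% of
the sample post-break — the tightest split the 15% trimming rule admits;
the empirically observed break date itself sits a few days inside that
bound, which is an inconsistency of the reference analysis, not of this
package. A fourth, structurally inert AR(1) count column fills the CSV
slot of the citizen group outside the model.

The round-clamp observation step deliberately discretizes: on a series that
is zero on ~88% of days, `asinh(round(sinh(g)))` destroys most
within-regime variation, and estimates from counts are attenuated (the
worked example in the README shows this). That mirrors the approximation
inherent in running a linear SVAR on transformed counts. Consequently the
*linear-stage* recovery claims (coefficients within 3 bootstrap SEs,
bootstrap size and coverage) are validated on the latent panel the
generator exposes, while break-date recovery and the qualitative
sign/ratio check run on the full count path through the reader and
transform. Passing tests therefore show the estimation chain is correct for
the model it assumes; they do not show the linear model is a faithful
description of integer count data, nor anything about any particular real
dataset.

## Problem sizes and defaults

Validation runs use T = 5000 (50 seeds, B = 199) for coefficient recovery,
T = 639 — the length of a Jan 2015–Sep 2016 daily sample — for break
recovery, size, and coverage checks, and B = 199 replicates in tests versus
the B = 500 default in production runs. Degenerate inputs fail loudly:
constant columns, covariances that are not positive definite, regimes with
fewer than 10 rows, unstable companion matrices, double differencing, and
calendar gaps all raise typed errors rather than propagating silently.

## Known limitations

- No day-of-week seasonality, holidays, or spatial structure (none in the
  model this package implements).
- At most two volatility regimes feed identification; richer regime
  structures are detected but not consumed.
- The smallest-‖δ‖ root convention can mislabel shocks when cross-effects
  rival own-effects.
- The break-date confidence band and the 2-sd ≈ 95% reading of IRF bands
  are approximations and labelled as such in outputs.
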