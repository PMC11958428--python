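# Methods

## Model and assumptions

The package analyses fixed-*n* Bayesian *t* tests of a point null
H₀: δ = 0 against a composite H₁ described by a proper prior on the
standardized effect size δ (= μ/σ for one sample, (μ₁−μ₂)/σ with equal
variances for two samples).  The sampling model is normal data with unknown
variance; with the usual Jeffreys prior on σ the marginal distribution of
the *t* statistic given δ is noncentral *t* with `v` degrees of freedom and
noncentrality `m·δ`, where `v = N−1, m = √N` (one sample) or
`v = n₁+n₂−2, m = √(n₁n₂/(n₁+n₂))` (independent samples).  Everything in the
package — Bayes factors, predictive probabilities, sample sizes — is built
from this one likelihood by one-dimensional numerical integration over δ.
No normality assumption is placed on the effect-size *estimate*; this is
what distinguishes the approach from the z-test-style comparator
implemented in `tpe_normal_approximation`.

Out of scope by design: sequential (open-ended *n*) designs, Welch's test
(its df depend on the observed variances and are unknowable pre-data), and
data-dependent priors such as fractional Bayes factors.

## Priors

Four families serve both as analysis prior (inside BF₁₀) and design prior
(generating the predictive distribution): point, scaled-*t* (df = 1 is the
Cauchy default with scale 0.707), normal, and the non-local normal-moment
density `(δ−μ)²/(√(2π)τ³)·exp(−(δ−μ)²/2τ²)` with modes at `μ ± √2 τ`.

One-sided hypotheses are implemented as hard truncation at δ = 0 with
renormalization, for every family including the normal-moment prior.  The
truncation point is the null value (not the prior location) because
directional hypotheses are directional about the null.  This convention
reproduces all published one-sided sample sizes we test against (43, 200,
55, 164, 48 per group; 86.3%).  Sampling is inverse-CDF throughout — the
normal-moment quantile goes through the Maxwell (chi with 3 df)
representation of |δ−μ|/τ — so draws are reproducible and exact.

## Numerics

Two evaluators compute the marginal likelihood
`p(t) = ∫ T_v(t|mδ) π(δ) dδ`:

1. **Adaptive scalar route** (`log_marginal_t`): peak-centred adaptive
   quadrature of the log-space integrand over the window
   `t/m ± 35·√(1+t²/2v)/m` intersected with the prior support.  The window
   is justified by the mixture representation `T = (Z+mδ)/S`,
   `S = √(χ²_v/v)`: as a function of the noncentrality the likelihood is a
   scale mixture of unit normals centred at `t·s`, hence has Gaussian tails
   of scale `√(1+t²/2v)`.  Target relative accuracy 1e−9; used for root
   polishing and any scalar query.
2. **Vectorized mixture route** (`MarginalMixture`): exchanging the order
   of integration gives `p(t) = (1/m)∫ s·g_v(s)·ρ(ts/m) ds` with ρ the
   prior convolved with N(0, 1/m²).  log ρ is precomputed once on a grid of
   step 0.03/m (closed form for point and untruncated normal priors;
   beyond `|y| > |loc| + 25·scale + 50/m` the smoothing is negligible and
   log ρ = log π analytically), and each evaluation is a Simpson rule in
   `s` with step 0.2/max|t|, grouped into |t|-magnitude blocks.  Only
   Gaussian arithmetic appears in the hot loop, so 10⁵ evaluations cost
   seconds.  Log-space accuracy is ~5e−5 in the evidentially relevant range
   and degrades to ~1e−2 only in tails hundreds of log-units below the
   mode, where no probability lives.

scipy's noncentral-*t* (Boost) is used wherever it is stable; its sporadic
failures (−inf in deep tails, exceptions for extreme argument
combinations) are caught and redirected to a log-space quadrature of the
defining normal/chi mixture, so every density evaluation is finite whenever
the true value is representable.

**Critical regions.** The sets {BF₁₀ > b} and {BF₀₁ > b} are found by a
sign-change scan of ln BF₁₀ on a fixed grid (dense on |t| ≤ 8, geometric out
to |t| = 50) using the mixture evaluator, followed by Brent refinement and a
Newton polish against the adaptive evaluator (residual tolerance 1e−10 in
ln BF, i.e. |t| error well below 1e−6).  If no grid point crosses a level,
the extremum between the two best grid points is polished before declaring
the bound unattainable — a flagged result, not an error.  Beyond |t| = 50
the Bayes factor is treated as constant-signed; a crossing out there could
in principle be missed for near-degenerate designs with single-digit
degrees of freedom, where the predictive mass beyond 50 is at most ~10⁻³,
and is ignorable for every design with v ≳ 10 (mass < 10⁻¹⁵).

**Region probabilities.** Predictive probabilities are computed as a 1-D
outer quadrature over δ of exact noncentral-*t* CDF differences (never a
2-D quadrature), with absolute tolerance 1e−9; scaled-*t* priors are mapped
through δ = loc + scale·tan(u) so their heavy tails integrate over a finite
interval.

**Sample size search.** Integer-exact: geometric doubling from n = 2 until
the target TPE is met (capped at n_max = 100 000 per group, matching the
practical ceiling beyond which a design question is better re-posed), then
integer bisection.  Minimality is verified by construction (the bisection
invariant keeps a failing size adjacent to the returned one).  TPE(n) is
not assumed globally monotone: any evaluated size above the returned n that
falls back below the target is reported in the result's `notes` and as a
warning.  Continuous root-finding followed by rounding can differ from the
integer-exact answer by one unit when TPE(n) grazes the target; the search
here resolves such ties exactly (e.g. it returns 287 per group where
TPE(287) = 0.800005), so a ±1 discrepancy against rounded reference values
is expected behaviour, not error.

**Unbalanced designs.** The allocation ratio r = n₂/n₁ fixes
n₂ = ceil(r·n₁) during the search, guaranteeing at-least-target TPE at the
reported n₁.  Fixed even totals split equally; an odd total puts the extra
observation in group 1.

**Normal-approximation comparator.** `tpe_normal_approximation` keeps the
exact critical region but replaces the H₁ predictive by
t ~ N(μ_δ·m, 1 + m²σ_δ²), the closed-form law that follows when the effect
estimate is treated as normal with known variance.  It is defined only for
point and untruncated normal design priors.  The exact and approximate TPE
agree to two decimals by n = 1000 per group in the scenarios we test, and
disagree by whole percentage points for n ≤ 20 — the approximation
understates TPE at small n because the exact predictive has heavier tails.

## Monte Carlo oracle

`simulation` re-derives every probability from first principles: δ drawn
from the design prior by inverse CDF, raw normal observations at population
scale σ (the t statistic is σ-free; σ is configurable only to make that
invariance testable), the t statistic computed from sample moments, and the
draw classified by its *exact* Bayes factor against ±ln b — not by the
critical region — so a single comparison validates the Bayes factor, the
region logic, and the outer quadrature at once.  Estimates carry binomial
standard errors; analytic values are required to sit within 4 SE at 10⁵
draws (≈99.99% coverage, so the suite stays deterministic-green).  What the
oracle emulates is exactly the model the analytic method assumes — normal
data, equal variances, effects from the stated prior; passing it therefore
certifies the computation, not the realism of the normal-data assumption
for any particular application.

## Known limitations

- Accuracy of the bulk evaluators is tuned so probabilities are reliable to
  ~10⁻⁵ absolute; do not quote more than four decimals.
- For designs with v < ~10 combined with evidence bounds reachable only at
  |t| > 50, region boundaries beyond the scan window are not searched (see
  above).
- The normal-moment prior's one-sided form is the truncated-at-zero
  renormalization; other conventions (e.g. truncating at the location)
  would change one-sided non-local results.
- Power-curve sweeps recompute each size independently; for very long
  grids at large n this is the dominant cost (~1 s per size at n ≈ 10³).
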