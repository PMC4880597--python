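# Methods

## Problem and model

Given per-axon diameter measurements x₁…xₙ (micrometres) from a white-matter
region, the package asks which of sixteen parametric families best describes
their distribution. Each family is fitted by maximum likelihood and scored
with the finite-sample-corrected AIC,

    AICc = 2k − 2 ln L + 2k(k+1)/(n − k − 1),

where ln L is the maximized log-likelihood and k the number of estimated
parameters; families are ranked by ascending AICc. BIC (k ln n − 2 ln L) and
the negative log-likelihood are computed alongside; at the sample sizes
involved (thousands of axons) all three criteria order the families
identically except across near-ties, and the tests assert exactly that.
Ranked tables from several datasets are then compared with Friedman's test
(midrank tie correction, χ² reference with k−1 df) and the Nemenyi post-hoc
critical difference.

## The sixteen families

Parameterizations follow the conventions of the axon-morphometry literature:
gamma is shape–scale; log-normal parameters live on the log scale;
exponential takes the rate λ of λe^{−λx}; the inverse Gaussian is
(mean μ, shape λ); Nakagami is (shape m ≥ ½, spread Ω = E[X²]); the
generalized extreme value (GEV) family is (location μ, scale σ, shape ξ)
with ξ > 0 giving the heavy right tail relevant here. The two-parameter
"extreme value" family is deliberately the minimum-type (left-skewed)
Gumbel — the convention of the major statistics toolboxes — and is distinct
from the GEV; on right-skewed diameter data it is expected to rank last, and
does. Numerics are delegated to `scipy.stats` (including the exponentially
scaled Bessel path that keeps the Rician log-density finite at high ν/σ);
this module contributes the uniform interface, the constraint rules
(e.g. Nakagami m ≥ ½, t location-scale ν ∈ [0.5, 1000]) and the sign
convention mapping (scipy's `genextreme` shape is −ξ).

Families with physically implausible shapes for diameters (Rician, Nakagami,
logistic, normal, …) are fitted anyway: the point of the comparison is that
the criterion, not prior belief, rejects them.

## Fitting

Closed-form MLEs are used for the normal, log-normal, exponential and
Rayleigh families (the σ̂-type estimators use the n-denominator, as MLE
requires). All other families are maximized numerically:

* **Objective**: mean negative log-density; observations outside a candidate
  support (possible for GEV/generalized Pareto shapes) yield −∞ likelihood,
  implemented as a large finite penalty so the simplex can retreat.
* **Search space**: positive parameters are log-transformed; the
  generalized-Pareto threshold is parameterized as μ = min(x) − e^u so it
  stays below the sample minimum while remaining a fitted parameter; the
  t location-scale degrees of freedom are logit-bounded to [0.5, 1000]
  (a bound hit is flagged in the fit message, not treated as failure);
  Nakagami's m is offset-log-transformed to respect m ≥ ½.
* **Initialization**: per-family method-of-moments recipes (e.g. gamma from
  (x̄/s)² and s²/x̄; log-scale logistic/Weibull starts from log-moments; GEV
  from the Gumbel moment solution with ξ₀ = 0.1). The generalized-Pareto
  start checks that its implied support covers the data and falls back to a
  mildly heavy tail (ξ₀ = 0.1) otherwise — a negative moment-based shape can
  otherwise exclude the largest observations and strand the optimizer.
* **Optimizer**: Nelder–Mead, relative tolerance 1e−8, at most 500·dim
  iterations, with 5 restarts by default (moment start plus seeded Gaussian
  jitter of SD 0.3 in the transformed space, i.e. multiplicative jitter on
  positive parameters). The best restart is kept and is never worse than the
  moment start. A fit whose restarts all fail returns `converged=False`
  rather than raising, so a ranking can always be produced; such families
  are listed as excluded with a reason instead of being ranked.

Ties in AICc are broken by smaller k (parsimony) and then family name;
internal scores keep full precision and reports additionally emit the
integer-rounded AIC column conventional in published ranking tables.

## Error profiling

The empirical CDF uses the standard right-continuous step form with tied
values collapsed. `cdf_error_profile` reports F̂(x) − Fₙ(x) on an even grid
over [min x, max x]; the sign convention (model minus empirical, positive =
over-estimated cumulative mass) is frozen here. Density overlays use
equal-width histogram bins on the density scale, defaulting to 100 bins —
smooth at n ≈ 20 000 — with the fitted densities evaluated at bin centers.

## Rank comparison

The Friedman statistic is computed from column rank sums with the standard
tie correction 1 − Σ(t³−t)/(mk(k²−1)); a fully tied matrix short-circuits to
statistic 0, p = 1. The Nemenyi quantiles q_α(k) are a frozen table for
k = 2…20 and α ∈ {0.01, 0.05, 0.10} (Studentized-range quantiles at infinite
degrees of freedom divided by √2); other α values are rejected rather than
interpolated. The packaged cross-species matrix (7 datasets × 6 families)
gives χ²_F = 29.61, p ≈ 1.8 × 10⁻⁵, and a GEV–gamma mean rank difference of
5.0 against a critical difference of 2.85 at α = 0.05. The χ² reference is
asymptotic in the number of blocks; with 7 blocks its type-I error at
α = 0.05 sits near 0.04 (measured by simulation in the tests), which is the
accuracy the procedure is used at.

## Synthetic data

The generator exists so every pipeline stage is testable without the real
measurement tables. The corpus-callosum-like preset draws from
GEV(μ = 0.45 μm, σ = 0.15 μm, ξ = 0.2) — values chosen once to match the
published summary moments of mouse corpus callosum diameters (mean ≈ 0.56,
SD ≈ 0.27, median ≈ 0.49 μm), not fitted estimates from any dataset — with
region sizes genu 7680, body 5260, splenium 7188 and rejection truncation to
the observed 0.03–3.09 μm range. Per-region seeds derive as
seed + CRC32(region), so adding a region never perturbs existing ones.

What the preset emulates: scale, right skew, heavy tail, realistic per-region
sample sizes, a common generating process across regions. What it does not:
region-to-region shape differences (real genu/body are more skewed than
splenium), measurement error and shrinkage artifacts, within-region axon
subpopulations, and spatial correlation between neighbouring axons. Passing
recovery tests on it therefore demonstrates that the estimation and selection
machinery is correct, not that any family is true of real tissue.

Recovery experiments: `parameter_recovery` reports bias, RMSE, Monte-Carlo
SE and 3-SE coverage per parameter, counting (never silently dropping)
non-converged replicates; `model_recovery` tabulates rank-1 frequencies and
the fraction of replicates in which the generating family is within a
configurable AICc margin of the winner (margin 2 = the usual
"indistinguishable from best" reading).

A note on nested competitors: when the generating family is a special case
of a rival (exponential inside gamma), Wilks' theorem puts the rival ahead
of the ~2-unit AICc penalty in roughly 16% of replicates no matter how large
n grows; recovery expectations in the tests are set at that level rather
than near-certainty.

## Problem sizes and numerical choices

Default experiment sizes — 50 replicates at n = 20 000 for GEV parameter
recovery, 50 replicates × 16 families at n = 7000 for model recovery, 2000
simulated 7 × 6 matrices for the Friedman null, 1 restart inside replicated
experiments (the moment starts are reliable at these n; multistart matters
for single fits of multimodal families) — were chosen as the smallest sizes
at which Monte-Carlo error is comfortably below the effects being measured.
Quadrature normalization checks split the support at the median to keep
adaptive integration accurate for heavy tails. Degenerate inputs are
rejected early: samples need n ≥ 2, strictly positive finite values and
non-zero variance; AICc requires n > k + 1.

## Limitations

* The measured-data reproduction requires the external measurement tables;
  it is a separate, clearly flagged test and CLI path.
* The generalized-Pareto fit treats the threshold as a free parameter bounded
  by the sample minimum; profile-likelihood alternatives for thresholds are
  out of scope.
* No censoring, truncation-aware likelihoods, or mixture models: the
  comparison is among the sixteen plain families.
* Nemenyi quantiles are tabulated for k ≤ 20 treatments at three α levels
  only.
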