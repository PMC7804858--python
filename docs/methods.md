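# Methods

This note records the modelling choices behind `cohoprior`, in the order the
pipeline applies them.

## The reduced structural equation model

The analysis needs a joint posterior over (i) the strength of the
urbanization–mortality relationship and (ii) each subbasin's current
urbanization score. We model both with a reduced latent-factor structure:
a single latent urbanization factor *Z* drives a small set of landscape
covariates (the measurement model) and, through a logistic link with a
subbasin random intercept, the binomial count of pre-spawn deaths among
surveyed spawners. Five covariates stand in for the much larger covariate
panels used in field studies; the downstream procedure only consumes the
one-dimensional posterior of *Z*, so measurement dimensionality is
incidental. Seasonal rainfall is deliberately absent: the analysis holds
precipitation at its mean and asks only how risk varies with urbanization.

Identifiability of a latent factor requires fixing its scale and sign. We
give *Z* a standard-normal prior (scale), constrain the mortality slope
*b* > 0 by sampling on the log scale, and truncate the first loading at zero
(sign). The invariance of the likelihood under (λ, z, b) → (−λ, −z, −b) is
thereby broken and all draws live in one mode.

Priors are weakly informative and configurable (`PriorSpec`): loadings
Normal(0, 2); covariate noise SDs and the slope HalfNormal(2); the intercept
population mean Normal(0, 3) on the logit scale and its SD HalfNormal(1).
At the sample sizes used (tens of subbasins, ~50 spawners each) the
likelihood dominates all of them.

## Sampling

No probabilistic-programming framework is used; the sampler is an adaptive
random-walk Metropolis-within-Gibbs written for this posterior's structure
(`cohoprior.sampler`). Per sweep:

1. **Latent moves** (vectorised across subbasins, applied three times per
   sweep): a random-walk move of *z*<sub>j</sub> along the ridge where the
   linear predictor *a*<sub>j</sub> + *b z*<sub>j</sub> is held fixed; an
   independence proposal for *z*<sub>j</sub> from its measurement-model
   conditional Normal(*m*<sub>j</sub>, *v*) with the same compensation; and
   a random walk on the intercepts.
2. **Scalar global updates**: each loading, noise SD, the slope, and the
   intercept mean/SD get an adaptive 1-D random-walk update (target
   acceptance 0.44).
3. **Group moves** for the known slow directions: a scale move exploiting
   the exact likelihood invariance *z* → *cz*, λ → λ/*c*, *b* → *b*/*c*
   (acceptance involves only priors and the Jacobian *c*<sup>J−K</sup>); a
   funnel move rescaling the intercept spread jointly with τ; and a location
   move shifting all intercepts jointly with μ<sub>a</sub>.

Step sizes adapt by Robbins–Monro during warmup only, so the post-warmup
kernel is fixed and draws are valid MCMC output. Defaults are 4 chains ×
(3,000 warmup + 1,500 draws); a fit at 60 surveyed subbasins takes roughly
20 s on one CPU core.

Convergence is summarised by classic split-R̂ and bulk ESS (via `arviz`)
over every parameter block including all per-subbasin latents; a fit with
max split-R̂ > 1.05 is flagged `converged = False` and downstream stages
refuse to consume it unless forced. The pipeline retries a non-converged fit
up to twice with a doubled warmup/draw budget and a deterministically
derived seed, because the failure mode observed in practice is a single
slow-mixing latent coordinate rather than a structural problem. Chain
initialisation is data-informed but jittered (covariate row sums for *z*,
empirical logits for intercepts) so chains start dispersed within the
identified mode.

## Out-of-sample subbasins

Most subbasins have covariates but no spawner surveys. For each posterior
draw, *Z* | covariates is the conjugate normal
`v = 1/(1 + Σ λ_k²/σ_k²)`, `m = v Σ λ_k x_k/σ_k²`, and we *sample* from it
(seeded) rather than taking the mean, so measurement uncertainty survives
into the threshold step — as the covariates become uninformative the *Z*
posterior widens to the prior SD of 1. Mortality predictions for these
subbasins draw an intercept per posterior draw from that draw's population
Normal(μ<sub>a</sub>, τ): the certainty level α therefore reflects full
parameter and random-effect uncertainty, not a point estimate.

## Threshold inversion and ΔZ

With *b* > 0 every posterior draw's mortality curve is strictly increasing
in *Z* and crosses *M*_crit exactly once, at
`z*_i = (logit(M_crit) − a_i)/b_i`. The exceedance probability
`P(M ≥ M_crit | z)` is then the empirical CDF of the crossing points, and
Z_crit — defined by exceedance = 1 − α — is their (1 − α) empirical
quantile. We use the inverse-empirical-CDF (type 1) quantile rule for both
this and the α-quantile of *Z*_cur, so both defining probability statements
hold exactly in the step-function sense; the rule is configurable. A
bisection solver on the empirical exceedance function is retained as an
independent cross-check path and agrees within one 10⁻⁴ step (the only
discrepancies are one-ULP float effects exactly at a crossing point).

ΔZ = Z_crit − Q_α(Z_cur). ΔZ < 0 classifies a subbasin as restoration,
ΔZ > 0 as preservation. The measure-zero boundary ΔZ = 0 is assigned to
preservation (no restoration effort is required there); the assignment is an
argument, not a constant. Both monotonicities used in the sensitivity
analysis are exact consequences of this construction: crossing points
increase in *M*_crit, and quantiles are monotone in their level, so ΔZ is
non-decreasing in *M*_crit and non-increasing in α draw-set by draw-set.

Defaults *M*_crit = 0.3 and α = 0.95 reflect the mortality level associated
with ~70-year extinction horizons for otherwise healthy coho populations and
a conventional high-certainty level; the sensitivity grid spans
*M*_crit ∈ [0.2, 0.4] and α ∈ [0.8, 0.99].

## Prioritization

The score is the Euclidean distance from (ΔZ, metric) to the ideal point
(0, metric_max), with metric_max taken over the whole analysis population
(both categories). ΔZ enters squared: the distance interpretation requires
it, and a linear ΔZ term would not even be dimensionally coherent under the
root. Because ΔZ (latent SD units, O(1)) and habitat (km, O(100)) are
incommensurate, the default `scaled` axis mode divides ΔZ by the population
maximum |ΔZ| and the metric by metric_max before measuring distance. This
differs from plain min-max normalisation on purpose: it keeps the ideal
point itself fixed at (0, 1), so a subbasin at the ideal still scores
exactly zero. A `raw` mode applies the distance to unscaled axes for users
who want the formula verbatim; in raw mode the km axis dominates. Ranks are
assigned per category, ascending in score, ties broken lexicographically by
subbasin id so rankings are invariant to input row order.

Ranking comparisons report both the mean signed and the mean absolute rank
change over the subbasins common to both rankings, plus how many changed
category — whether a "mean rank change" should be signed is ambiguous, so
both are computed.

## Future-development scenarios

A subbasin is flagged under a scenario when it is currently in good
condition — imperviousness strictly below 10% (the literature's impairment
threshold) *and* predicted mortality below 0.10 — but the scenario's
projected imperviousness reaches ≥ 10%. "Predicted mortality" is the
posterior median of *M* evaluated at the subbasin's posterior-median *Z*;
the summary statistic is configurable since other conventions (posterior
mean, upper quantile) are defensible. The area summary reports flagged area
and flagged fraction of an explicit eligible universe (by default, the
preservation subbasins with ΔZ > 0 and current imperviousness < 10%). Both
comparison directions are strict/non-strict exactly as stated; flagging is a
pure per-row function, so it is permutation-invariant and idempotent.

## The synthetic generator

`GeneratorConfig` defaults describe the study system the pipeline is sized
for: 1,400 subbasins (a Puget-Sound-scale region) of which 60 carry spawner
surveys of 50 fish; five covariates with loadings 0.6–1.0 and noise SD 0.5;
mortality intercepts Normal(−2, 0.5) on the logit scale (≈12% mortality at
*Z* = 0) and slope 1.5, so predicted mortality crosses the 0.2–0.4
*M*_crit band in the middle of the latent range. Imperviousness is a
logistic squashing of *Z* onto [0, 100]% centred at *Z* = 2, which places
roughly 40% of subbasins under the 10% impairment threshold; scenario
futures multiply current imperviousness by 1.15 (managed), 1.5 (status quo)
and 2.0 (unconstrained), capped at 100%. Habitat-km are lognormal — the
marginal shape is a free choice, nothing downstream depends on it beyond
positivity and right skew — with Chinook habitat present in a Bernoulli(0.5)
subset of coho subbasins and only weakly correlated (ρ = 0.3 on the log
scale) with coho habitat, so the two metrics genuinely disagree about
priorities.

What the generator does *not* emulate: spatial autocorrelation between
subbasins, stream-network topology, temporal survey structure (surveys are
aggregated to one count pair per subbasin), and real covariate panels.
Passing tests therefore demonstrate that the inferential machinery is
correct under the model's own assumptions, not that those assumptions hold
in any particular landscape.

## Numerical details and degenerate inputs

- All randomness descends from explicit integer seeds;
  `numpy.random.SeedSequence` children separate stages, and fixed seeds give
  byte-identical CSV artifacts.
- Binomial log-likelihoods use `log_expit` for stability at extreme linear
  predictors; exceedance limits are exact 0/1 by ±20 latent units.
- If 1 − α falls below the 1/S resolution of the posterior, `solve_z_crit`
  warns and returns the boundary crossing point.
- An all-zero metric column yields an empty analysis population with a
  warning, not an error; an empty eligible universe yields an NaN flagged
  fraction, reported as such.
- Tables are validated on load (counts, bounds, id uniqueness, Chinook ⊆
  coho habitat) with 1-based CSV line numbers in error messages.
- The persisted posterior CSV is thinned per chain (default ≤ 100 draws per
  chain) to bound artifact size; in-memory analysis always uses the full
  draw set.

## Problem sizes

Default test and acceptance runs use 60 surveyed subbasins for fits, 300
subbasins for fixture-level analyses, and the full 1,400-subbasin region for
the end-to-end pipeline; the slope-recovery simulation uses 20 replicates at
2 chains × (2,000 warmup + 750 draws). These sizes give stable diagnostics
and complete in minutes on a single core.

## Known limitations

- The random-walk sampler mixes more slowly than gradient-based samplers;
  very small survey counts or many more covariates would warrant longer
  chains.
- Credible-interval coverage for the slope is slightly below nominal at the
  default problem size (17–15/20 replicates covering at 90%), consistent
  with modest-ESS MCMC and a hierarchy estimated from 60 groups.
- ΔZ is a latent-scale proxy for effort; converting it to cost requires
  information the model does not carry.
- The Chinook analysis reuses coho-derived ΔZ values; a species-specific
  dose–response would change both thresholds and ranks.
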