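# Methods

## The problem

Counts of insects (the motivating system is wild bees surveyed in urban
parks, half of which received a habitat-restoration treatment) confound two
processes: how many individuals are present, and how likely each one is to
be detected. If a site-level driver such as restoration affects detection as
well as abundance, a naive count model attributes both effects to abundance.
`countmix` implements three estimators of the community-mean effect of a
binary site treatment on abundance, a generator of synthetic survey data
whose assumptions can be violated in controlled ways, and a protocol that
measures each estimator's bias and precision across scenario grids.

The unit of analysis is one site x species x year combination, indexed `i`,
with `J` repeated surveys (default 3) per unit.

## Models

All three models share the log-linear abundance predictor

    log lambda_i = alpha1[species] + alpha2[site] + alpha3 * year
                   + alpha4[species] * restored_i

with species intercepts `alpha1 ~ N(mu_alpha1, sigma_alpha1)`, species
restoration slopes `alpha4 ~ N(mu_alpha4, sigma_alpha4)` and site intercepts
`alpha2 ~ N(0, sigma_alpha2)`. `mu_alpha4` — the community-mean restoration
effect on abundance — is the estimand throughout. The detection models use
the analogous logit-linear predictor for `p_i` with a `beta` block.

**GLMM.** Every per-survey count `y_{i,j}` is an independent negative
binomial draw with mean `lambda_i` and dispersion `phi`
(variance `lambda + lambda^2/phi`). Detection is not modelled; whatever the
treatment does to detectability is absorbed into `alpha4`.

**binmix** (binomial N-mixture). Latent abundance `N_i ~ NB(lambda_i, phi)`
(a Poisson mode is available), counts `y_{i,j} ~ Binomial(N_i, p_i)`
independent across surveys given `N_i`. The latent count is marginalized by
a log-sum-exp-stabilized finite sum from the largest observed count of the
unit to a bound `K_i`.

**multimix** (multinomial mark-recapture mixture). Individual detection
histories over `J` surveys are tallied into the `2^J - 1` observable
categories (for J = 3, fixed column order 111, 110, 101, 100, 011, 010,
001). Writing `pi_c(p)` for the product-Bernoulli probability of history
`c` and `pi_0 = (1-p)^J` for the all-zero history, the likelihood
factorizes into a multinomial over observable cells conditional on the
number observed `n_i` (cell probabilities `pi_c / (1 - pi_0)`) and a
marginalized `n_i ~ Binomial(N_i, 1 - pi_0)` with `N_i` summed from `n_i`
to `K_i`. Marginalization rather than sampling of the discrete `N_i` is a
structural contract of the package, independent of the inference backend.

**The bound K.** The default rule is `K_i = (lower_i + 5) x 12` with
`lower_i` the unit's largest count (binmix) or `n_i` (multimix). The
additive convention `K_i = lower_i + 100` used by other N-mixture software
is available as `KRule.unmarked()`, and both addend and multiplier are
configurable end-to-end (estimators and grid runners take a `k_rule`).
The printed form of the default rule is ambiguous between `(c + 5) x 12`
and `c + 5 x 12`; we adopt the former, larger reading, and treat the
choice as immaterial by *testing* K-insensitivity (doubling the multiplier
must leave likelihoods within 1e-8 and fitted posterior means within
Monte-Carlo error) rather than assuming it.

K-insensitivity holds whenever the bound comfortably exceeds the bulk of
the latent abundance distribution, but it **fails by design in the closure
experiment**: there the superpopulation is large (`lambda ~ 55-190` at
restored sites) while the observed `n_i` that anchors the bound is small
under low availability, so `K_i ~ 84` truncates real NB mass, and it does
so asymmetrically (restored units are hit harder when restoration lowers
availability). Our diagnostic at the hardest closure cell shows the
truncation accounts for most of both models' restoration-effect bias
there: under a stability-escalated bound (multiplier 36, unchanged at 72)
the multimix estimate is essentially unbiased and the binmix bias shrinks
by more than half. The evaluation grids nevertheless default to the
printed rule, because the comparative results they are designed to
reproduce carry the same truncation; rerunning any grid with
`k_rule=KRule(addend=5, multiplier=36)` quantifies the effect.

## Inference

The engine targets the log posterior over the full hierarchical parameter
vector: community means, all species/site deviations, log-scale SDs, and
`log phi`.

**Priors** (defaults; the exact hyperparameters used in the original field
analysis are not published, so these are the package's own weakly
informative choices, overridable via `PriorSpec`): normal(0, 2) for every
location parameter on the log/logit scale, half-normal(0, 1) for each
random-effect SD, and half-normal(0, 1) on `1/sqrt(phi)` for the NB
dispersion (allowing the Poisson limit).

**map mode** (the desk-scale default). L-BFGS-B with analytic gradients;
the gradients of the marginal sums are posterior expectations over the
latent `N`, computed from the same normalized weights as the likelihood.
Joint maximization of a hierarchical posterior is degenerate in the
random-effect SDs (the density diverges as any sigma -> 0 with its
deviations fully pooled — the "funnel"), so the SDs are never given to the
optimizer. Instead the engine alternates (i) optimization of all other
parameters with SDs fixed and (ii) a closed-form empirical-Bayes update of
each SD from the deviations' sum of squares plus their conditional
posterior variances (diagonal Laplace curvatures) — an EM iteration whose
E-step is the Laplace approximation. Four iterations with a 5e-3
convergence window suffice in practice. On simulated GLMM data this
procedure reproduces glmmTMB's marginal-ML fixed effects and variance
components to two decimals (see the cross-check test).

Uncertainty comes from a Laplace approximation: the Hessian of the negative
log posterior (forward differences of the analytic gradient), inverted over
the free coordinates; SDs and bound-pinned coordinates are held at their
point estimates, so reported intervals are empirical-Bayes intervals
conditional on the estimated variance components. 250 draws (configurable)
from this Gaussian stand in for posterior samples so that the evaluation
pipeline is exercised identically in both modes.

**mcmc mode.** Affine-invariant ensemble MCMC (emcee), initialized in a
tight ball around the MAP. Walkers are treated as chains for the R-hat and
ESS diagnostics (arviz); a fit with any R-hat above 1.05 or ESS per draw
below 0.1 is flagged `non_mixing`, never silently accepted, and grid
runners drop flagged fits with a logged count. Divergence counts are
recorded as zero — ensemble moves have no divergence concept — and the
diagnostic defaults (4000 iterations, 2000 discarded) follow the field
protocol the models mirror. The ensemble sampler shares the funnel
geometry of the centered parameterization, so mcmc mode is intended for
small models and checks, not for the evaluation grids.

**Posterior predictive checks.** For each retained draw the fitted model
simulates a replicate dataset; the Bayesian p-value is the fraction of
replicates whose discrepancy statistic exceeds the observed one (ties count
half). Statistics: total count (default) and the variance/mean ratio, which
detects overdispersion misfit of a Poisson abundance model.

## Synthetic data

The generator mirrors the models' structure exactly when closure holds:
Poisson (default) or NB abundance per unit, logit-linear detection,
per-survey Bernoulli detection per individual, tallied both into history
categories and per-survey counts from the same individual records (so the
two views are consistent by construction, which is asserted, not assumed).

Closure violations are produced by an availability process: individual `k`
at unit `i` is inside the sampled area on survey `j` with probability
`theta_i = logit^{-1}(theta0 + theta1 * restored_i)`, drawn independently
per individual x survey (temporary emigration; an unavailable individual
cannot be detected). Marginally each individual is detected with
probability `theta_i p_i` independently across surveys, so both mixture
models remain formally well-specified with an *effective* detection rate —
the estimators differ in how well the data identify it: history tallies pin
the effective rate through recaptures, repeated counts barely do, which is
the mechanism behind the binmix results below.

Scenario grids fix the community means; values not specified by any
scenario are package defaults chosen once as realistic for a multi-species
insect survey: `sigma_alpha1 = sigma_beta1 = 0.5` (species heterogeneity),
`sigma_alpha2 = sigma_beta2 = 0.25` (site heterogeneity),
`sigma_alpha4 = 0.25` (slope heterogeneity), `alpha3 = beta3 = 0.25` (year
effects), and `sigma_beta4 = 0` (no species heterogeneity in the detection
response to treatment, since the scenarios vary only the community mean).
The generator emulates the statistical structure of real repeated-count
data but not, e.g., phenology within a survey window, observer effects, or
spatially structured movement — availability is exchangeable across
individuals — so passing tests demonstrate estimator behaviour under the
stated model, not robustness to every field reality.

## Evaluation protocol

For each scenario cell and model, `n_replicates` datasets are simulated and
fitted, and 250 draws of each target parameter per fit are pooled. Bias
draws are `draw - truth` (truth: restoration effect 1, and the abundance
intercept in the closure experiment); a cell reports their mean, central
90% quantile interval, and precision = 1 / sample SD (n-1 denominator; with
thousands of pooled draws the denominator convention is immaterial, but it
is pinned by a unit test). Non-converged or non-mixing fits are dropped and
counted.

The three experiments: a detection grid (`mu_beta1` in {-3,-2,-1,0} x
`mu_beta4` in {-0.5,0,0.5,1}, abundance intercept 2, 20 sites), a sites
grid (10/20/30 sites, `mu_beta1 = -2`), and a closure grid (`theta0`,
`theta1` in {-1,0,1}, abundance intercept 3 — a larger superpopulation in
the surrounding landscape — detection intercept -2, no detection
confound). Default design: 16 species, 2 years, 3 surveys. Full-scale runs
use 20 replicates per cell; the shipped tests and the acceptance script run
5-8 replicates per cell in map mode, which keeps the whole protocol at
desk scale while leaving the pooled-draw machinery identical.

## Numerical choices and edge cases

- Detection probabilities are clipped to [1e-12, 1 - 1e-12] before logs;
  linear predictors cannot reach 0/1 but user-supplied fixed `p` can.
- The latent sums share one `N` grid per fit (0..max K) with per-unit
  masks; the binomial-coefficient matrices are parameter-independent and
  precomputed once per fit.
- `log sigma` is bounded in [log 0.01, log 5] and `log phi` in
  [log 0.05, log 1000]; EM updates are clipped to the same box.
- A zero-SD pool of draws is flagged degenerate and reports an infinite
  precision sentinel rather than dividing by zero.
- Laplace factorization retries with escalating ridge terms and falls back
  to a diagonal approximation on pathological curvature; coordinates pinned
  at bounds are excluded from the Gaussian.
- Site and species identifiers are arbitrary labels; they are factorized
  internally and preserved in draw column names.

## Known limitations

- map-mode intervals are Gaussian approximations conditional on
  empirical-Bayes variance components; they understate uncertainty when a
  posterior is strongly skewed (low detection, small data) relative to full
  MCMC.
- The ensemble sampler is a diagnostic-grade MCMC for small models, not a
  replacement for gradient-based samplers on the full hierarchy.
- Open-population dynamics beyond exchangeable temporary emigration
  (births, deaths, behavioural responses to capture) are out of scope, as
  are distance-sampling observation models.
- The multinomial mixture generalizes to any `J >= 1`, but the shipped
  column-naming convention targets small `J` (bit-string columns).
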