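# Methods

## Model

Each modelled indicator A ∈ {any use, modern use, unmet need} is a
unit-level Bernoulli-logit mixed model for married/in-union women aged
13–49:

    y_{A,ed,i} ~ Bernoulli(p_{A,ed,i}),
    logit p_{A,ed,i} = x_{ed,i}' β_A + v_{A,ed},   v_{A,ed} ~ N(0, σ_A²),

with one random intercept per (ethnic group, state) domain *ed*. The model
is deliberately simple: a single variance component per indicator, no
crossed or nested structure, no survey weights in the likelihood (weights
enter at the benchmarking stage; a weighted pseudo-likelihood is available
behind `weighted=True` but is off by default). Some statements of this
model add a Normal individual error term ε alongside the Bernoulli
response; a logistic GLMM has no separate residual, so ε is absorbed into
the Bernoulli variation. A per-domain variance σ²_{ed} would be
unidentifiable with one intercept per domain; one σ_A per indicator is
used.

The covariate codebook fixes 20 dummy columns plus intercept: seven
five-year age bands (reference 45–49), motherhood, three education levels
(reference: none), not attending school, working, poor wall material, house
or apartment, electricity, internet, same-ethnic partner, ethnic
self-identification (Afro-descendant or Indigenous), and the ethnicity ×
same-ethnic-partner interaction. The reference profile maps to the zero
vector, so the intercept is the log-odds for that profile.

## Estimation

Because the random effect is scalar per domain, the marginal likelihood
factorizes into one-dimensional integrals approximated by the Laplace
method at the conditional mode v̂_d (found by damped Newton, vectorized
across domains):

    ℓ_d(β, σ) = h_d(v̂_d) − log σ − ½ log(Σ_i p_i(1−p_i) + 1/σ²).

Maximization is over (β, log σ) with an analytic gradient — envelope
theorem for h, implicit differentiation of v̂ inside the log-determinant —
verified against finite differences in the test suite. L-BFGS-B provides
the bulk of the progress; a Newton polish (finite-difference Hessian of the
analytic gradient, Levenberg-style damping) then drives the gradient
infinity-norm below the tolerance, 1e-8 by default. The `converged` flag
reports exactly that criterion; non-convergence is flagged, never silent.
Standard errors come from the inverse observed information of the Laplace
objective. σ is bounded below at 1e-6 on the log scale; a solution pinned
at the boundary is reported as σ = 0 (the fit then coincides with plain
logistic regression, which the tests verify against an independent IRLS
oracle). Complete separation of the outcome by a binary covariate raises an
error naming the covariate. lme4's `glmer` (Laplace, nAGQ = 1) maximizes
the same objective; one test cross-checks the two implementations on a
small fixture.

**ICC.** The intraclass correlation uses the latent-threshold convention
for logistic models, ICC = σ²/(σ² + π²/3), i.e. the between-domain share of
latent variance with the logistic residual fixed at π²/3. Its confidence
interval is a nonparametric cluster bootstrap: domains are resampled with
replacement (each draw treated as a distinct cluster), the model refitted,
and the 95% percentile interval taken over replicate ICCs; non-convergent
replicates are dropped and counted. A caveat established during
development: with few, small clusters σ̂ is biased low on a nontrivial
share of datasets and the percentile interval inherits that bias —
empirical coverage was ≈0.80 with 42 small domains but ≈0.95 with 75
domains. The bootstrap is therefore trustworthy only when the variance
component is reasonably well determined.

## Census prediction

p̂ = logistic(x'β̂ + v̂_{ed}) per census woman, computed in log-odds space
and transformed once (no overflow for extreme linear predictors). Domains
present in the census but absent from the survey use v̂ = 0 — prediction
from fixed effects only, the conventional SAE fallback — and are logged. A
categorical level never observed at fit time raises an error rather than
extrapolating. Need satisfied is derived per woman as
p̂_NS = p̂_modern/(p̂_any + p̂_unmet); because the three models are fitted
independently the ratio can exceed one, in which case it is clipped with a
logged count, while the three raw probabilities are left unclipped for
aggregation. A zero denominator raises; the caller decides exclusion. At
domain level the default aggregation is the (weighted) mean of individual
ratios, matching the individual-level definition; the ratio of aggregated
means is available via `ns_aggregation="ratio_of_means"`.

## Benchmarking

Direct estimates D_{A,j} are Hájek means Σwy/Σw from the survey at each
level j (national, each state, rural, urban); for need satisfied the direct
estimate is the weighted demand ratio Σw·y_modern / Σw·(y_any + y_unmet).
The adjustment ratio is R_j = D_{A,j}/Ŷ_{A,j} with Ŷ the unweighted census
mean of the predictions. Since the R_j conflict across overlapping levels,
a single weight set per indicator is calibrated so that every level's
weighted prediction mean equals D_{A,j}: each constraint is met exactly by
an exponential tilt w_i ← w_i·exp(λ(p̂_i − D_j)) on its members — the
chi-square-minimal adjustment for a Hájek ratio constraint — cycling
through states, rural, urban, national (last, as it is near-redundant given
the states). Cyclic raking alone converges linearly with a rate close to
one on this overlapping system, so after 30 sweeps a joint Newton solve on
the tilt multipliers (a K-dimensional smooth root-finding problem, K =
number of constraints) finishes the job quadratically; on the six-state
fixture all residuals reach ~1e-9 within ≈32 iterations. Default residual
tolerance 1e-8; default weight bounds [0.2, 5] prevent degenerate tilts,
with clip events logged; an infeasible system returns a non-converged
solution with a per-constraint residual report and a warning. Whether one
weight set should serve all four indicators is ambiguous in the source
description; one set per indicator is the default here.

## Bootstrap MSE

The parametric bootstrap for unit-level models: per replicate, draw
v* ~ N(0, σ̂²) for every domain, simulate outcomes on survey and census
rows from logistic(x'β̂ + v*), take the bootstrap truth as the realized
census domain proportion, refit on the bootstrap survey (warm-started at
the original estimates, gradient tolerance relaxed to 1e-6), re-predict and
re-aggregate, and average squared deviations over replicates. Replicates
live on independent seed substreams (`SeedSequence.spawn`), so results are
invariant to execution order. Non-convergent replicates are dropped and
counted; fewer than B/2 survivors is a hard error. B defaults to 200. The
default measures the model-based estimator; `benchmark=True` recalibrates
weights inside every replicate to measure the benchmarked estimator, at
roughly four times the cost. The joint variant generates all three outcomes
hierarchically (below) so the derived need-satisfied indicator has a
coherent bootstrap truth. Output tables report both √MSE/estimate
(`rrmse_pct`) and MSE/estimate (`rel_mse_pct`), as "error below x% of the
estimate" is ambiguous between the two readings.

## Synthetic data

The generator emulates the joint structure of the real inputs: states ×
three ethnic groups × rural/urban cells with configurable sizes, covariates
drawn independently per cell from categorical/Bernoulli marginals with
realistic gradients (education, housing quality, electricity and internet
decline from non-ethnic urban to Indigenous rural; same-ethnic partnership
≈ 2/3 for ethnic women, 0.9 for non-ethnic), outcomes from the logit
linking model, and a stratified simple random sample per state × urbanicity
stratum with inverse-inclusion-probability weights.

Defaults define the study conditions: the published coefficient vectors as
true β_A; σ_A chosen to match the published latent-scale ICCs (0.076,
0.070, 0.058 ⇒ σ ≈ 0.520, 0.498, 0.450); six states of 2,000 women; 25%
sampling. The three models are marginal, so a joint outcome law is built
hierarchically: draw any-use from its model, modern use among users with
conditional probability p_modern/p_any capped at one, unmet need among
non-users with p_unmet/(1 − p_any) capped at one. This enforces the
consistency invariants (modern ⊆ any; unmet ⇒ non-user) by construction and
reproduces all three marginals wherever the caps do not bind; cap events
are counted and logged (with the published coefficients the modern/any cap
binds for roughly 15% of rows, since the independently specified modern
model exceeds the any-use model for some profiles).

What passing tests on these data do **not** establish: the generator draws
covariates independently within cells (no realistic joint dependence, e.g.
education × age), uses a clean stratified SRS rather than a multi-stage
cluster design, has no nonresponse or measurement error, and its outcomes
truly follow the fitted model family — so the tests validate the
estimation machinery, not robustness to model misspecification or to real
survey complexities.

## Problem sizes and numerical choices

Test and acceptance runs are desk-scale by design: the six-state fixture
(12,000 census rows, ≈3,000 survey rows, 18 domains) for calibration and
MSE checks; n = 50,000 with 20 replicates for coefficient recovery; 200
outer Monte-Carlo replicates vs B = 100 for the MSE calibration check; the
ICC coverage study at 75 domains, B = 100, 20 outer replicates. Ties and
degenerate inputs: empty benchmark levels and empty domains are reported as
undefined/NaN rather than silently zero; classification metrics with an
empty class return None rather than NaN; zero sampling fractions, zero
weights, B < 2, and unknown categories are rejected at the boundary.

## Limitations

- One variance component per indicator; no municipality-level or crossed
  random effects (the published analysis found finer disaggregation
  non-convergent as well).
- Unmet need and current use are treated as mutually exclusive states
  (standard DHS semantics), enforced in validation and in the generator,
  relaxable via `exclusive_unmet=False`.
- The in-union filter expects an explicit 0/1 column; no inference of union
  status from raw partnership variables.
- No analytic (Prasad–Rao) MSE approximation; uncertainty is bootstrap-only.
- Direct estimates are taken as fixed benchmarks; their own sampling
  variance is not propagated.
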