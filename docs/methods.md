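# Methods

## Problem and model

`splitcar` estimates area-level prevalence from a complex survey over a
study region whose adjacency graph has two or more connected components
("regions"). The observation model is the empirical-logit Gaussian
approximation: for each sampled area *j*,

    y_j^L ~ N(eta_j, var_logit_j),    eta_j = x_j' gamma + v_j + u_j,

where `y_j^L = logit(p_hat_j)` is the logit of the design-weighted
(Horvitz–Thompson / Hájek) prevalence and `var_logit_j` is its
delta-method design variance, **treated as known**. `v_j` is iid Gaussian
with precision `tau_v`; `u_j` follows a scaled intrinsic CAR prior with
precision matrix `tau_u * R`, `R = D - W` built from 0/1 contiguity
weights. The fixed part is a common intercept or one intercept per region,
plus optional standardized area-level covariates.

The model variants (I, II, III, IVa, IVb, V) differ only in how the
intercept, the sum-to-zero constraints, the ICAR scaling, and the
random-effect precisions treat the split map; see the README table. In
the split variants each region receives its own `tau_u,r` and `tau_v,r`,
and the joint precision matrix is block-diagonal across regions apart from
any shared fixed effects — which is why, with separate intercepts and no
shared covariates, the joint fit reproduces the separate per-region fits
exactly (an identity the acceptance suite checks to 1e-6 and typically
observes at 1e-14).

## Survey reduction

* Prevalence: `p_hat = sum(y*s)/sum(s)` — the weighted ratio form. It is
  invariant to rescaling all weights in an area and reduces to the sample
  mean under equal weights.
* Design variance: Taylor linearization of the ratio estimator with the
  with-replacement first-stage convention — residuals `z_i = s_i (y_i -
  p_hat) / sum(s)` are totalled per PSU (or left per record when no PSU
  labels exist) and `var = m/(m-1) * sum(z^2)` over the `m` units.
  Finite-population corrections and stratum df adjustments are omitted.
* Degenerate areas (`p_hat` in {0,1}, a single PSU, or a design variance
  below 1e-12 — exact cancellation of PSU residuals can produce a
  spuriously zero variance): by default a continuity correction adds 0.5
  pseudo-successes and 0.5 pseudo-failures at the average weight and
  floors the variance at the binomial `p(1-p)/n` of the corrected
  estimate; alternatively the area is excluded (treated as unsampled).
  The default keeps every sampled area in the likelihood.

## ICAR scaling and constraints

Marginal variances of the intrinsic field under the per-component
sum-to-zero constraint are the diagonal of the Moore–Penrose pseudo-inverse
of each component block of `R`. Each scaling group (the whole graph for
`global`, each component for `per_component`) is rescaled by the geometric
mean of those variances, making the post-scaling geometric mean exactly 1
so `1/tau` reads as a marginal variance. For the 3-node path the factor is
`(50/729)^(1/3) = 0.40934`. Global scaling pools the geometric mean over
all areas of all components. Graphs with singleton components are
rejected explicitly — the models here require every region to have at
least two areas.

Constraints are one row of ones (`single`) or one indicator row per
component (`per_region`). Unstructured effects carry no constraint.

## Inference

Conditional on the log-precisions `theta`, the posterior of the latent
field `x = (gamma, v, u)` is Gaussian: `Q(theta) = Q_prior + Z_obs' D
Z_obs` with `D = diag(1/var_logit)`. Constraints `A u = 0` are imposed by
conditioning by kriging using sparse LU solves. Because the ICAR block is
singular exactly along the constrained directions, the factored matrix is
augmented with `c A'A`; on the constraint subspace this changes neither
the constrained distribution nor the corrected marginal likelihood (the
`log|Q| + log|A Q^{-1} A'|` combination is invariant to `c`), and it makes
prediction-only systems well posed.

The log marginal likelihood at each `theta` is closed-form:
`log pi(x*) + log p(y|x*) - log pi_c(x*|y)` at the constrained posterior
mean, with the ICAR prior density taken in the generalized sense (rank
`n - #components` per block, generalized determinant). Theta-independent
measure constants cancel in the grid weights.

Hyperparameters get independent Gamma(0.5, rate 0.005) priors. The
posterior over `theta` is explored on an adaptive grid in standardized
coordinates from the Hessian at the mode (BFGS search, curvature floored
so flat directions are explored out to ~5 sd): best-first expansion keeps
points whose log-density is within 5 of the mode, with per-dimension step
0.5 sd for up to two hyperparameters and 1.0 sd for more (the split models
have four; the coarser step keeps the point count in the hundreds, and the
self-convergence check shows halving the step moves fitted prevalences by
under 1e-5). An explicit grid can be supplied instead — that is how the
split-fit equivalence is made exact, by fitting model IVb on the product
of the two per-region grids.

Marginals of every latent component and every `eta_j` (sampled or not) are
grid-weighted Gaussian mixtures with closed-form moments; interval
endpoints come from bisection on the mixture CDF. Fitted prevalence is
the posterior mean of `expit(eta_j)`, by default via seeded Monte Carlo
(seed 20150101, 5,000 draws) with a deterministic Gauss–Hermite
alternative (`method="ghq"`) used wherever exact reproducibility matters.

## Model comparison

The deviance is defined on the observed Gaussian summaries only, with the
linear predictor as focus: `p_dic = sum_j Var[eta_j]/var_j` and
`dic = D(E[eta]) + 2 p_dic`. WAIC uses the exact per-component convolution
`N(y; m_g, var_j + s_g^2)` for the lppd and Gaussian fourth-moment
identities for `p_waic`. Both also have seeded Monte Carlo paths used as
cross-checks. On the unit-Gaussian toy the closed forms are
`log 2pi + 2` and `log 4pi + 1`. Effective-parameter monotonicity across
nested models holds in the bulk of replicates but not pointwise — the
grid discretization perturbs `p_dic` by a few hundredths.

Forward stepwise selection adds, per round, the single covariate term
(plain or region-interacted) with the largest DIC decrease above a
threshold (default 0), removing the whole covariate family from the
candidate list once one of its forms is accepted.

## Synthetic data

The generator emulates the intended study conditions: two rook-adjacent
rectangular lattices (default 12x7 + 8x7 = 140 areas echoing an 87 + 57
district split), area prevalences `expit(alpha_r + beta x_j + u_j + v_j)`,
and a two-stage stratified cluster survey. Strata are region x
urban/rural with per-area urban shares ~ U(0.25, 0.95); each area holds 12
PSUs of 30–60 children; PSUs are drawn with replacement proportional to
size (each draw an independent replicate, matching the with-replacement
variance estimator), and 7 children are taken per PSU hit — 217 draws per
stratum give ~868 PSUs and ~6,000 children, the scale of a national
survey round. Weights are inverse inclusion probabilities; unequal
weights arise across strata and from small PSUs. By default 12.5% of
areas are removed from the frame to mimic districts with no samples.

Scenario magnitudes, chosen once as realistic study conditions: intercepts
near `logit(0.24) = -1.17`; structured marginal variances 0.05 and 0.20
across regions (a clearly present spatial signal at the scale a joint BYM
fit reports for such data, with the factor-4 regional contrast the split
models target); unstructured variance 0.05–0.06; the `shifted_baseline`
scenario moves the intercepts to (-0.9, -1.5); `covariate_effect` adds one
standardized covariate with slope -0.101, a deliberately weak,
realistic magnitude — recovery of *strong* effects (|beta| ~ 0.5+) is what
the stepwise tests exercise.

What the generator does **not** emulate: real geography, population
rasters, non-response, weight trimming/raking, more than four strata, or
individual-level covariates. Passing tests therefore demonstrate the
correctness and calibration of the machinery under a faithful idealization
of the design, not robustness to those real-data complications.

## Numerical choices and limitations

* Observation variances are fixed/known; with few PSUs per area they are
  noisy in truth, which is the main reason interval coverage on synthetic
  data sits slightly below nominal (~93–95% against the 95% target) —
  inherent to the empirical-logit approach, not to this implementation.
* The flat intercept prior is a proxy precision of 1e-12; covariate slopes
  get precision 0.001 on the z-scored scale.
* Mode search: BFGS with numeric gradients, log-precisions clipped to
  [-20, 20] with a quadratic pull-back; grid log-density cutoff 5;
  exploration capped at ~6 sd per direction.
* Marginal variances come from sparse-factor solves against the needed
  right-hand sides (never an explicit dense inverse of the joint
  precision); dense algebra appears only in test oracles and in the
  small-system constrained sampler.
* Problem sizes throughout tests and the acceptance script (140-area maps,
  tens of replicates for aggregate assertions, 100 for coverage) were
  picked to make the statistical assertions stable at desk scale.
* DIC/WAIC use the latent-field focus; a hyperparameter-focus DIC is not
  implemented.
* Distance-based or k-nearest-neighbour weight matrices are out of scope;
  contiguity is queen (default) or rook.
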