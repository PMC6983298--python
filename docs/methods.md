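# Methods

## The model

`hierdsm` fits a density surface model (DSM) to double-observer line-transect
survey data in one stage. The study region is divided into spatio-temporal
analysis units (grid cell x period); for unit *i* the expected number of
*groups* sighted is

    E(n_i) = p_i * A_i * exp(B0 + sum_j f_j(X_ij)),

where `A_i` is the searched area (km^2), the `f_j` are penalized spline
smooths of habitat covariates `X_ij`, and `p_i` is the survey-specific
detection probability. All components below are estimated **jointly** by
MCMC, so detection, availability and group-size uncertainty propagate into
the posterior of every density and abundance summary.

### Detection

Surface detectability uses the point-independence mark-recapture
distance-sampling (MRDS) estimator

    theta_i = g(0, z_i) * (1/W) * int_0^W g(y, z_i) dy,

with a half-normal `exp(-y^2 / 2 sigma(z)^2)` or hazard-rate
`1 - exp(-(y/sigma(z))^(-b))` key function, a log-linear scale model
`sigma(z) = exp(z' c)`, and a logistic conditional-observer model
`p(y, z) = logistic(d0 + d_y y + z' d)` fitted to the two-observer capture
histories. With two observers scored independently at the trackline the
platform probability is `g(0,z) = 1 - (1 - p(0,z))^2`; in a trial
configuration (one team scores the other) it is `p(0,z)` itself.

Shipboard sightings contribute both a conditional distance density
`g(y,z)/esw(z,W)` and the capture-history likelihood. For the aerial
platform the rear team's obstructed view precludes trackline estimation from
the histories, so aerial `g(0)` is a free parameter with an informative beta
prior (mean 0.67, CV 0.16) and aerial sightings contribute the distance term
only. Diving animals are handled by a surface-availability probability `a`
with a beta prior (mean 0.37, CV 0.34; moment-matched from the published
mean/CV); the cell-level detection probability is `p_i = theta_i` for ship
and `p_i = theta_i * a` for aerial platforms. Shipboard availability is
fixed at 1 by assumption.

### Density-habitat surface

Each smooth is `f(x) = sum_k beta_k b_k(x)` with basis size `K` (default 5)
and a quadratic penalty `gamma beta' S beta`. Two families are provided:
cubic regression splines (values-at-knots parameterization with the exact
integrated-squared-curvature penalty; natural boundary conditions, hence
linear extrapolation beyond the knots) and 1-D thin-plate splines
(`r^3/12` radial basis on the constrained subspace plus a linear term).
Knots sit at quantiles of the observed covariate (evenly spaced optional).

Identifiability with the intercept comes from absorbing the sum-to-zero
constraint into a reparameterization (the training design columns sum to
zero). The prior on the smooth coefficients is the multivariate normal with
**precision** `sum_k gamma_k S_k`. Because each `S` is rank-deficient, a
rank-completing penalty on its nullspace (with its own `gamma`) makes the
precision proper; both smoothing parameters get conjugate
`Gamma(0.05, 0.005)` priors (shape-rate, prior mean 10) and exact Gibbs
updates `gamma | beta ~ Gamma(0.05 + rank(S)/2, 0.005 + beta'S beta / 2)`.

### Count likelihood

Counts are compound Poisson-gamma (CPG), the Tweedie family with power
`rho = (alpha+2)/(alpha+1) in (1, 2)`: a Poisson number of groups-events
`G_i ~ Poisson(lambda_p)` each contributing a `Gamma(alpha, alpha/lambda_g)`
mass, so `E(Y) = lambda_p lambda_g`, with an exact zero atom
`P(Y=0) = exp(-lambda_p)`. The split-coefficient regression

    lambda_p = exp(X(beta - phi)/2),   lambda_g = exp(X(beta + phi)/2)

keeps `E(Y) = exp(X beta)` for any `phi`. MCMC augments the latent counts
`G_i`, drawn exactly from their discrete full conditional over a support
window widened until the tail mass is below 1e-12. A truncated series-sum
marginal density (terms below 1e-14 of the running sum dropped after the
mode) serves as an independent oracle in the tests, never in the fit.

Design choices the data could not decide:

* **Offset placement.** The detection/effort offset `log(p_i A_i)` enters
  the Poisson intensity only (default): thinning a count process scales the
  event rate, not the per-event mass. A "split" mode (half the offset in
  each exponent) is available; the two agree in the mean and differ only in
  variance allocation.
* **Dimension of phi.** All design columns carry split coefficients by
  default, as the regression parameterization defines them; a config switch
  restricts `phi` to the intercept. The restriction is not innocuous for
  integer counts: it ties the per-event gamma mean to the habitat smooth
  (`lambda_g,i = exp((B0 + f(x_i) + phi_0)/2)`), and because an
  integer-valued response pins `lambda_g` near 1 in every cell, the
  likelihood then shrinks the smooth's amplitude well below what a REML
  Tweedie fit recovers on the same data. With the full `phi` the two agree.
* **Prior on alpha.** `log alpha ~ N(0, 10^2)` truncated to `alpha <= 5`
  (`rho >= 1.17`). The truncation is a numerical necessity discovered in
  development: for integer-valued counts the *continuous* CPG density is
  unbounded as `alpha -> inf` (the per-event gamma collapses onto the
  integers at the Poisson boundary `rho -> 1`), so an unbounded prior lets
  `alpha` drift indefinitely and freezes the regression blocks. For
  genuinely continuous responses the bound is essentially never active.

### Group size

Observed group sizes are modeled as `(s_t - 1) ~ Poisson(lambda_s)` — a
unit-shifted Poisson, exactly as the abundance model defines it (not the
renormalized truncated pmf) — with mean group size `lambda_s + 1`, a vague
`Gamma(0.01, 0.01)` prior, and an exact conjugate Gibbs update. Group size
is assumed unrelated to detection probability.

### Abundance

Per retained draw, the offset-free group density is
`D_i = exp(B0 + sum_j f_j(X_ij))` (detection divides out at prediction, so
grid cells need no effort) and the individual abundance is
`N_i = (lambda_s + 1) D_i A_i^G` with `A_i^G` the cell area; totals are
per-draw sums, so all posterior correlations reach the total's CV.

## Sampler

Blockwise MCMC: exact Gibbs for `gamma_k`, `lambda_s` and the latent `G_i`;
adaptive random-walk Metropolis (Robbins-Monro scale adaptation toward
acceptance 0.3, frozen after burn-in, bounded log-scale) for the intercept,
each smooth's coefficient block, `phi`, `log alpha`, the per-platform
detection blocks, `logit a` and `logit g0_aerial` (bounded parameters are
sampled on the logit scale with the beta prior evaluated exactly, Jacobian
included). Detection blocks are initialized at the stand-alone
maximum-likelihood MRDS fit when at least 10 sightings exist; the intercept
starts at `log(total count / total offset)`; up to 100 jittered restarts
guard against a non-finite start. Draws are reproducible given (seed,
config); chain seeds derive from `SeedSequence([seed, chain])`.

No feedback-cutting is applied between the detection and habitat blocks:
correlation between them is an expected, reportable feature of the joint
model (detectability estimates typically drift above the stand-alone MRDS
fit when the habitat model is included).

## Two-stage comparator

Stage 1 fits the detection model per platform by maximum likelihood
(BFGS with restarts; covariance from the central-difference observed
information; delta-method CVs for the mean distance-component probability,
mean `g(0)` and their product). Stage 2 reuses the same Bayesian spatial
machinery with every first-stage component frozen at its point value, so
stage-2 spread is spatial-model-only. Variance propagation is `none`
(historical practice) or `delta`:
`CV_total^2 = CV_spatial^2 + sum_c CV_c^2` over the independent first-stage
components (per-platform detection, availability, mean group size), with a
lognormal 95% interval. Independence between stages is assumed, which is
why the simulation study deliberately uses simple scenarios.

## Variance-component experiment

The hierarchical model is refit once per fix-set in {none, lambda_s,
availability, detection_ship, detection_aerial, all}, each run freezing the
named component at its point estimate (seed policy: base seed + 1000 x run
index). The report lists N-hat, CV and the percent change in CV against the
full run, `100 (CV_fixed - CV_full) / CV_full`; conditioning on a component
can only remove variance, so every entry is weakly negative up to Monte
Carlo error.

## Synthetic-data generator and what the tests show

The simulator draws one habitat covariate per cell, iid uniform on (-2, 2),
and sets the true log-density to `B0 + sin(pi x / 2)` (a +/-1 log-range, a
realistic magnitude of habitat contrast for a baleen-whale surface), with
baseline density 0.04 groups km^-2 on a landscape of 10 x 10 km cells —
chosen so a 300-cell survey yields on the order of 150-200 sightings,
comparable to a single-species large-whale survey. Line-transect sampling
runs one 10 km line per surveyed cell with truncation W = 1 km, half-normal
detection (sigma = 0.5 km), two observers with equal conditional-detection
coefficients (d0 = 1.2, d_y = -0.5), availability 1 for the default
ship-only design, and group sizes `1 + Poisson(0.4)` (mean 1.4). Group
presences in the searched strip are Poisson; a present group at distance
`y ~ U(0, W)` is detected with probability `a g(y) g(0)` and its capture
history follows the conditional independent-Bernoulli split at `p(y)` —
exactly the fitted observation model, so calibration failures indicate
estimator defects, not generator mismatch. Under the `cpg` count family the
continuous draw is rounded to the nearest integer to give a group count.

What the generator does **not** emulate: spatial autocorrelation beyond the
covariate, covariate measurement error, responsive movement, species
misclassification, duplicate-identification errors and availability
correlated with behavior. Passing tests therefore demonstrate internal
consistency of the estimator under its own assumptions, not robustness to
these real-data features.

The replicated study scores each method's 95% interval against the
landscape-total true abundance (the prediction task over all cells).
Problem sizes used in the tests and acceptance script: 10 replicates of a
400-cell landscape with 300 surveyed cells and chains of 6,000 (2,000
burn-in, thinning 5, two chains) — a smoke version of the full desk-scale
study (100 replicates), which `hierdsm simulate --reps 100` reproduces.
At 10 replicates the binomial 99% band around nominal 95% coverage is 8-10 of 10,
and the bias check widens by the Monte-Carlo standard error of the
replicate mean.

## Numerical choices

* Half-normal effective strip width is analytic
  (`sigma sqrt(pi/2) erf(W / sigma sqrt 2)`); hazard-rate uses 64-node
  Gauss-Legendre quadrature with a node-doubling convergence check
  (relative change > 1e-8 is an error, not a warning).
* Beta priors are moment-matched from (mean, CV); concentrations
  `alpha + beta > 1e8` are rejected as degenerate.
* Penalty matrices are symmetrized and eigen-checked (minimum eigenvalue
  >= -1e-10 relative); penalty ranks come from the same eigendecomposition.
* Spline prediction outside the knot range warns and extends each basis
  function linearly from the boundary.
* The Gelman-Rubin diagnostic is the split-chain variant: each chain is
  halved, `R-hat = sqrt((n-1)/n + B/(n W))` with B the between-half-chain
  variance of means (per-observation scale) and W the mean within-half
  variance.
* CVs are sd/mean and require a positive, sign-constant quantity.

## Known limitations

* The natural cubic regression spline cannot represent a quadratic exactly
  (f'' = 0 at the boundary knots); reproduction holds to an O(h^2) boundary
  layer. The thin-plate basis shares the piecewise-linear-curvature
  limitation.
* Fitting the continuous CPG to integer counts is a deliberate
  approximation (inherited from the model family); the alpha truncation
  above is its numerical consequence.
* The two-stage delta combination assumes independence of the first-stage
  components and the spatial fit.
* Basis size K is fixed by configuration; no automatic selection, tensor
  products, or spatial random effects.
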