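# Methods

## The scientific problem

Whether a pregnancy was wanted, mistimed or unwanted at conception is a
candidate determinant of whether the woman subsequently receives skilled
antenatal care (ANC).  The data structure is a national two-stage cluster
household survey: enumeration areas (clusters) sampled first, households
within clusters second, with survey weights correcting unequal selection.
Outcomes are two nested dichotomisations of ANC uptake for the most recent
live birth — at least one visit to skilled health personnel (`y_any`) and at
least four (`y_four`, the WHO recommendation at the time).  Because several
survey rounds preceded the analysis round, coefficient information from the
earlier rounds can be carried forward as informative priors.

## Model

For woman *i* in cluster *j*:

    logit P(y_ij = 1 | u_j) = x_ij' beta + u_j,   u_j ~ N(0, sigma_u^2)

Households are collapsed into the woman level: with roughly one analysed
woman per selected household a separate household variance component is not
identifiable.  Survey weights enter as a pseudo-likelihood — each woman's
log-likelihood contribution is multiplied by her weight, weights normalised
to sum to the sample size, inside the cluster integral.  Point estimates are
invariant to rescaling all weights by a constant.

### Maximum likelihood

The marginal likelihood integrates each cluster's random intercept by
*adaptive* Gauss–Hermite quadrature: nodes are centred at the cluster's
conditional mode (found by a damped Newton iteration on the log-concave
integrand, always started from u = 0 so the likelihood is a deterministic
function of the parameters) and scaled by the local curvature.  Nine nodes
are the default for ML, seven for MCMC; on small fixtures the quadrature
agrees with a 10^4-point Simpson rule to better than 1e-4.  Optimisation is
L-BFGS-B over (beta, sigma_u) with sigma_u bounded at zero; at sigma_u = 0
the likelihood reduces exactly to ordinary weighted logistic regression
(starting values come from a statsmodels GLM fit).  AIC = −2ℓ + 2k and
BIC = −2ℓ + k·log n count the variance parameter in k.  Complete separation
is reported (warning + flag), never silently repaired.

### Posterior sampling

The posterior over (beta, sigma_u) combines the weighted marginal
likelihood, independent normal priors on beta, and a half-normal(0, 5²)
prior on sigma_u (the scale 5 is essentially vague on the logit scale while
keeping the boundary proper; the analysis this package operationalises does
not state a variance-component prior).  The kernel is random-walk
Metropolis on the *integrated* parameter space — no latent u_j are sampled —
with a fixed multivariate-normal proposal whose covariance is the Laplace
approximation at the ML fit scaled by 2.38²/d; only the global step scale is
tuned (toward 23% acceptance) and only during burn-in, so kept draws come
from a fixed, valid kernel.  Chains start from jittered ML estimates.
Defaults are 3 chains, 5,000 burn-in and 10,000 kept draws; all tests and
the packaged configs use smaller, explicitly stated settings.

Correctness of the sampler is defined by equivalence to a deterministic
trapezoid-grid posterior (`exact_grid_posterior`, at most two free
parameters, ≤200 observations, with a grid-halving error estimate) and by
parameter-recovery/coverage simulations — not by the kernel choice.

### Summaries

Odds ratios are the posterior mean of exp(beta); intervals are equal-tailed
2.5/97.5 percentiles of the pooled exp(beta) draws (percentiles are
transformation-equivariant, so these are exactly the exponentiated
log-odds percentiles; software summarising exp of posterior-mean instead
will differ slightly — an accepted, documented divergence).  The latent
intra-class correlation is sigma_u²/(sigma_u² + π²/3), the standard
latent-threshold decomposition for the logistic link, evaluated at the ML
variance estimate for ML fits and at the posterior mean of sigma_u² for
Bayesian fits.

## Prior elicitation from historical waves

Each earlier wave is fitted with vague N(0, 10000) priors on every
coefficient.  Per coefficient, the informative prior is normal with

* mean — the average of the wave-specific posterior means;
* SD — the across-wave sample SD (n−1) of those means, **floored** at the
  average within-wave posterior SD.

The floor resolves an ambiguity in the moment rule ("the square of the
regression coefficient standard deviation" can be read across waves or
within wave): the across-wave spread is the primary reading because it
captures coefficient drift between rounds, while the floor guarantees a
proper prior when the waves agree exactly and caps the prior's sharpness at
what the historical fits themselves support.  Coefficients absent from the
historical fits (e.g. a category unobserved in an old round) fall back to
N(0, 10000) with a logged warning.  Elicited priors are always at least as
informative as the vague prior and the prior mean is invariant to wave
order.

## Screening and descriptives

Candidate confounders are screened against both outcomes with a
**Rao–Scott second-order corrected chi-square**: the Pearson statistic from
weighted cell proportions, referenced against a Satterthwaite-adjusted
chi-square using the eigenvalues of the estimated design-effects matrix
(cluster-linearised covariance).  The cluster covariance deliberately uses
denominator n_clusters (no finite-cluster factor) so that with equal
weights and one unit per cluster the test collapses *exactly* to classical
Pearson; at hundreds of clusters the omitted n_c/(n_c−1) factor is
negligible.  A variable is retained when p ≤ 0.20 for at least one outcome
(the usual purposeful-selection reading of a 0.20 screen); the exposure is
never screened out.  Weighted prevalences get logit-scale Wald intervals
with design-based variance, so bounds respect [0, 100] and collapse at the
boundaries.

## The synthetic survey generator

`generate_wave` emulates one survey round from a known truth: cluster
intercepts u_j ~ N(0, sigma_u²); cluster-level residence/region; household
covariates drawn from configurable category marginals, with an exponential
composition tilt across clusters for wealth and education (SD 0.8) so
community-level aggregates are non-degenerate; lognormal survey weights
(dispersion 0.2 by default, an unanchored free choice — design effects are
not published for these surveys) normalised to mean 1.  One eligible woman
per selected household.  Default design constants are the study's: 600
clusters × 30 households; eligibility (a live birth within 3 years and a
stated intention) uses p_recent_birth = 0.26 and p_missing_intention =
0.03, reproducing the observed ≈25% eligible (≈4,493 of 18,000).  The
intention mix defaults to 74.0/15.1/10.9%.

Both outcome codings are generated jointly: `y_four` from its own marginal
logistic model (separate slopes, or a shared-slope intercept shift of −1.35
calibrated to the observed 64%/31.5% prevalences), then `y_any`
conditionally so that its marginal model is exactly logistic and
`y_four ≤ y_any` always.  This requires eta_four ≤ eta_any row-wise, which
is validated (violations clipped with a warning).  Raw visit counts and
provider type are back-filled so the outcome coding rules recover the
generated outcomes exactly.

What the generator does **not** emulate: probability-proportional-to-size
frame selection, stratification and non-response; cross-covariate
correlation (covariates are independent given the cluster tilt); any real
"quality of ANC" construct (simulated as standard normal noise, since the
analysis lists it but never operationalises it).  Passing recovery tests
therefore shows the estimator is correct *under the stated model*, not that
the model captures every feature of the real surveys.

## Model ladder and diagnostics

Four nested specifications per outcome: M0 (cluster intercept only), M1
(individual + household factors), M2 (community factors only), M3 (all).
AIC/BIC come from the ML fit (they are not Bayesian quantities here), ICC
from the latent decomposition, convergence from the Gelman–Rubin potential
scale reduction factor (between/within-chain variance with the standard
finite-sample correction, non-split; flagged converged when Rc < 1.1 for
every parameter).  Preferred model: smallest AIC among converged fits, ties
broken by BIC.  Row-level failures leave a flagged partial table.

## Numerical and design choices

* Boundary conventions for the community cuts: low iff share ≤ 0.25,
  moderate iff 0.25 < share ≤ 0.50, high above — the published category
  labels overlap at the boundaries, and shares are continuous, so a
  half-open convention is adopted and tested.
* Community aggregates are leave-self-in (a woman's own response counts
  toward her cluster's category) and are computed over the eligible
  analysis rows of the cluster.
* Missing covariates: complete-case exclusion with a logged tally.
* Age categories (≤19, 20–34, ≥35) apply to age at the most recent
  delivery.
* All randomness flows from a single root seed split per stage; rerunning a
  pipeline config with the same seed reproduces every numeric artifact
  byte-for-byte.

## Problem sizes used in the packaged runs

The demo config runs 4 waves of 100 clusters × 10 households; the recovery
simulations run 50 replicates at 150 clusters × 30 women (the same ≈4,500
analysed women per replicate as the real analysis wave, with a
correspondingly smaller number of clusters); the acceptance script
simulates historical waves at 300 clusters and the analysis wave at the
full 600 × 30 design.  These sizes are the package's chosen trade-off
between Monte-Carlo precision and a run that completes in minutes on one
CPU.

## Known limitations

* The sampler is a single-block random-walk; for models much larger than
  the ~35 coefficients of the full specification, mixing will degrade and a
  gradient-based kernel would be preferable.
* The pseudo-likelihood treats weights as precision multipliers; it targets
  the census estimating equation but its Bayesian interpretation is
  approximate (as with all weighted Bayesian survey analyses).
* AIC/BIC compare ML fits, not the informative-prior posteriors.
* The published "quality of antenatal care" covariate and the printed
  Table-2 denominators are not reproducible from the publication and are
  deliberately out of scope.
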