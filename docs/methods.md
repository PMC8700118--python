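# Methods

## Data-generating process

Persons draw (theta, xi) from a bivariate normal with Var(theta) = 1,
SD(xi) = 1 and Cor(theta, xi) = 0.5. Item responses are 2PL with unit
discriminations and difficulties equidistant on [−2, 2] (endpoints
included); response indicators follow psi(xi − beta − delta·X) with a
common beta across items. The generator's defaults — N = 1500 persons,
I = 20 items, missing rates {5, 10, 20, 30}%, delta in {−10, −3, −2, −1,
0}, a linear fixed design (everyone sees every item) — are the study
conditions; SD(xi) = 1 is the package's own choice of unit scale for the
propensity (only the correlation is a design factor, and beta absorbs
the location).

beta is calibrated numerically: the expected missing proportion

    (1/I) sum_i E[ 1 − psi(xi−beta)·(1−P_i(theta)) − psi(xi−beta−delta)·P_i(theta) ]

is evaluated by 41-point Gauss–Hermite quadrature per latent dimension
and solved for the target rate with Brent's method on beta ∈ [−12, 12]
(the rate is strictly increasing in beta); the solution is verified to
1e−4. Monte-Carlo checks at N = 50k confirm realized rates within ~0.002
of target in every cell. Note the identification triangle at delta = −10:
since only incorrect responses can then go missing, a 30% overall rate
requires ~60% of incorrect responses missing — a very strong selection
regime. Reproducibility: one master seed per dataset, with sub-streams
for latents, responses and indicators derived via `SeedSequence.spawn`,
so each component is individually reproducible.

## Estimators

**2PL (treatments UW, UP, UN1, UO1, CD and stacked rescaling).**
Marginal maximum likelihood by EM over a fixed grid of 21 points on
[−5, 5] with renormalized standard-normal prior weights (the same grid
convention the joint models use per dimension). Missing entries
contribute nothing to the likelihood; fractional entries x ∈ (0, 1)
(partially-correct scoring, 1/K for a K-option multiple-choice item)
weight the expected success/failure counts — a pseudo-likelihood. The
M-step is a per-item Fisher-scoring Newton update with step halving,
vectorized across items; bounds a ∈ [0.05, 8], b ∈ [−8, 8] contain
boundary items (all-equal observed values are flagged, not fatal).
Convergence: relative log-likelihood change < 1e−9 or maximum parameter
change < 1e−5 (the looser 1e−6/1e−4 pair left linked means visibly
unconverged at these sample sizes), capped at 1000 iterations.

**Latent background model (UO2, UN2).** The prior over the grid becomes
person-specific N(gamma0 + gamma1·Z_p, sigma_e²) with Z_p the selected
missingness proportion. gamma is updated by weighted least squares on
posterior means, sigma_e from posterior-weighted residuals. The model is
estimated freely and the theta metric standardized afterwards (marginal
mean 0, SD 1, with a, gamma rescaled accordingly) so all treatments share
one identification convention. A constant covariate falls back to the
plain 2PL.

**Joint models (MO1, MO2, MW, MM1, MM2).** The three-category likelihood
(observed-wrong, observed-right, missing) is maximized by EM over the
441-node product grid. The prior weights are the bivariate normal density
at the nodes, reweighted each M-step from the current (SD(xi), Cor) by the
constrained complete-data MLE (Var(theta) fixed at 1, means 0): with
posterior second moments S, the regression slope c = S12/S11 and residual
variance tau² = S22 − S12²/S11 give Cov = c and Var(xi) = c² + tau²,
clipped to SD(xi) ∈ [0.05, 10], Cor ∈ [−0.99, 0.99]. The M-step for item
parameters updates all (a_i, b_i, beta_i) and the free delta(s) in a
single bounded L-BFGS call with analytic gradients (a generalized M-step);
delta is bounded to [−10, 3], the wrong-scoring model clamps delta = −10
exactly. beta is item-specific in all fitted models even though the
generator uses a common value.

The free-delta likelihood is multimodal: with strongly negative true
delta, an EM started at delta = 0 can converge to a spurious positive
mode in which the propensity part absorbs the missingness. The fit
therefore pilots the EM for 40 iterations from delta ∈ {0, −4, −9} and
continues the best pilot to convergence (relative log-likelihood change
< 1e−8 or parameter change < 1e−4, max 500 iterations). Starting values:
a = 1, b from observed logit difficulties, beta from observed missing
rates.

**Imputation (IW, IO1, IO2, IM1, IM2, IP, IF1, IF2).** Model-based
imputation draws one (theta*, xi*) node per person from the fitted 2-D
posterior, then imputes each missing cell Bernoulli at the Bayes-rule
probability P(X=1 | R=0, theta*, xi*); five imputed datasets by default,
stacked (rows keep their person weights) and rescaled with the 2PL rather
than pooled — standard errors are left to resampling. Guessing imputation
(IP) needs no model: missing MC cells are Bernoulli(1/K), CR cells 0.

FCS imputation cycles over incomplete columns (10 cycles per stored
dataset, chains initialized from marginal draws). The target column is
regressed on the other item columns (IF1) or the items plus all response
indicators except the target's own (IF2); predictors are compressed to
10 PLS factors (scikit-learn's NIPALS implementation, components capped
at the predictor rank, zero-variance columns dropped) and predictions
matched to the 5 nearest observed donors, one copied at random — so
imputed values always exist in the observed data. Donor count and cycle
count are the package's choices; results are insensitive to both in the
tested toys. A booklet grouping option runs the algorithm separately per
booklet; the simulation uses a single booklet.

## Linking and reporting

Haberman linking in two least-squares stages over common items: first
log a_ic = log a_i + log nu1_c, then nu1_c·b_ic + nu0_c = b_i, both
unweighted, with the reference group fixed to (nu0, nu1) = (0, 1); for
two groups this equals log-mean-mean linking (asserted against the
closed form). Because every group's scaling fixed theta to N(0, 1),
(nu0_c, nu1_c) are the group's mean and SD on the reference metric. In
the simulation the truth is the reference, so the linked (mean, SD) is
compared against (0, 1). The reporting transform applies one affine map
to all groups so the weighted pooled mean is 500 and the pooled SD
(within + between) is 100.

## Simulation summaries

Bias = mean(estimates) − truth; RMSE = root mean squared deviation from
truth. Monte-Carlo uncertainty uses a delete-one-zone jackknife with 20
zones assigned round-robin over replications:
SE = sqrt((G−1)/G · sum_g (s_(g) − s̄)²). Replication seeds derive from
the master seed and replication index (counter-based), so any cell can be
reproduced or parallelized independently. Failed fits would be excluded
with a logged count; none occur in the shipped configurations.

Problem sizes: the acceptance script runs the unidimensional treatments
at 500 replications and the bivariate joint models at 100 (a joint fit
costs ~1–3 s; 100 replications bound the Monte-Carlo SE of a bias near
0.004 while keeping the full run ~10 minutes). The test suite exercises
the same cells at 100–500 replications and the recovery study at 100.

## What the generator does and does not emulate

It emulates the measurement core of a large-scale assessment:
logistic item response functions, a latent response propensity driving
omissions, response-dependent (nonignorable) missingness, person weights,
multiple groups on separate metrics. It does not emulate multi-matrix
booklet designs (the administered mask is structural but booklet sampling
is not generated), polytomous items, position or not-reached dynamics
(not-reached classification exists for real data, but the generator
produces omissions only), response times, or country-specific item
parameter drift. Passing tests therefore speak to the estimators'
behavior under the stated missingness family, not to operational survey
complications.

Under this generator the qualitative ordering of treatments is stable
and is what the test suite asserts: complete-data and correctly
specified Mislevy–Wu fits are unbiased (the boundary cell delta = −10
with 30% missing included); scoring-as-wrong is unbiased exactly when
missingness can only arise from incorrect responses and grows strongly
negatively biased as delta approaches latent ignorability; ignoring
missingness and the latent-ignorable model are positively biased when
the response itself drives missingness, with the bias growing in the
missing rate. The magnitudes of these biases are reported by
`scripts/acceptance.py` and `analysis/03_bias_table.py` at run time.

## Known limitations

* The latent-regression identification (standardize after free
  estimation) is one of several defensible conventions; comparisons
  across packages should link item parameters rather than compare raw
  coefficients.
* GHP person-parameter counts for joint models attribute 3 parameters
  (a, b, beta) per administered item; the convention is configurable
  because no single standard exists.
* BIC uses n = persons; for stacked imputed data information criteria
  are intentionally not reported.
* The FCS imputation is serial per column and is the slowest component
  (~15 s per five-imputation run at N = 1500, I = 20).
* Haberman linking is unweighted; robust variants and linking-error
  estimation across item selections are out of scope.
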