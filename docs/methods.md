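# Methods

## Estimand and setting

The package targets the hypothetical estimand
θ = E[Y(Z=1,C=1)] − E[Y(Z=0,C=1)] in a two-arm randomized non-inferiority
trial with a continuous outcome and all-or-nothing compliance in both active
arms: a participant either receives their allocated treatment in full or
receives nothing; there is no switching between active treatments.  Higher
outcome is better, estimates are new minus standard, and non-inferiority is
declared when the lower limit of the two-sided 95% interval (one-sided
α = 0.025) lies strictly above the margin, −0.3 by default.  A bound exactly
equal to the margin does not declare; the tie is measure-zero but fixing it
keeps replays bit-reproducible.  Intervals use normal quantiles, not t
quantiles, throughout.  All estimators assume valid randomization,
consistency and no interference.

## Generative model

Covariates X (observed) and U (unobserved) are independent Bernoulli(0.5);
Bernoulli(0.5) allocation.  Compliance is logistic,

    logit P(C=1) = γ0 + γZ Z + γX X + γU U + γZX ZX + γZU ZU,

and the outcome is linear-normal in treatment received,

    Y = β0 + βC0 R0 + βC1 R1 + βX X + βU U + δX R1 X + δU R1 U + ε,
    ε ~ N(0, σ²),

with R0 = (1−Z)C, R1 = ZC.  A Z-by-X compliance interaction creates
*measured* confounding between compliance and outcome, a Z-by-U interaction
*unmeasured* confounding.  The heterogeneity terms δX, δU sit on the
received-new-treatment indicator, so the individual hypothetical contrast is
βC1 − βC0 + δX X + δU U and its population value is
θ = βC1 − βC0 + δX·pX + δU·pU.

### Scenario presets (reconstruction choices)

The headline facts fixed by the study conditions are: scenario A uses
n = 100, overall compliance 0.70, θ = −0.3, margin −0.3 (the boundary null,
so declaration rates are type-I errors); heterogeneity (TEH) scenarios use
n = 500 at the same compliance and θ.  Exact coefficient magnitudes are the
package's own reconstruction:

* β0 = 0, βC0 = 0.5, βC1 = 0.2, βX = βU = 0.5, σ = 1.
* |γX| = |γU| = 1 on the log-odds scale (≈20-percentage-point compliance
  spread across covariate levels); γZX or γZU = +2 where the
  covariate-compliance association has opposite signs in the two arms;
  γZ = +0.5 where the new treatment has higher compliance.  The intercept γ0
  is calibrated numerically (Brent root-finding on the exact expectation over
  the eight (Z,X,U) cells) so every preset's population compliance is 0.70
  to machine precision.
* TEH presets: δ = 0.25 (moderate) or 0.5 (large); the between-arm compliance
  difference is γZ = 0.5 (moderate, ≈10 points) or 1.5 (large, ≈30 points);
  βC1 is lowered so θ stays at −0.3.
* `A4a_eq` is the unmeasured-confounding scenario with γZ = 0: identical
  compliance models in both arms, the condition under which the Bayesian IV
  is insensitive to prior mis-centering.

Presets are plain frozen dataclasses; every coefficient is overridable via
`ScenarioConfig.replace`.

## Estimators — numerical conventions

**ITT / per-protocol.** OLS of Y on (1, Z, X) over everyone / over compliers,
classical standard errors.  Rank deficiency raises an error naming the first
collinear column.  Per-protocol requires at least one complier per arm.

**IPW.** The per-arm stage-1 logistic of C on (1, X) with binary X is
saturated, so its MLE fitted probabilities are computed exactly as the
per-(arm, X)-cell compliance proportions, including the separated limits 0
and 1.  Stage 2 is weighted least squares of Y on (1, Z) among compliers with
weights 1/p̂ and an HC1 sandwich covariance.  A fully compliant arm needs no
reweighting (all weights 1, no flag).  When compliance varies within an arm
but a cell is perfectly predicted (fitted probability outside
[1e−6, 1−1e−6]), the compliers of that cell are retained at the limit weight
1 and the fit is *flagged* with the count of observations that
drop-on-separation software conventions would remove; the replication filter
then excludes the whole replication from reported summaries.  This keeps
single-dataset results well defined (the hand-computable weighted means) while
reproducing the reported-subset convention at the summary level.

**Interaction IV (2SLS).** Endogenous (R0, R1), instruments (Z, Z·X),
exogenous (1, X); the model is just-identified.  Projecting the receipt
indicators on the instrument block reproduces the arm-specific stage-1
regressions with exact zeros in the opposite arm.  The residual variance
uses the original regressors with no degrees-of-freedom correction (the
conventional 2SLS default), and the contrast SE comes from the delta rule on
the 2SLS covariance.  A relative smallest singular value of the projected
design below 1e−8 raises an identifiability error — this is precisely the
condition that the predicted compliances are proportional across X levels
(full compliance in both arms is the canonical case).  Diagnostics record the
per-cell receipt rates, the stage-1 interaction strength, and the singular
values.

**Bayesian IV.** Stage-1 linear models C0 ~ (1, Z[, X]) and C1 ~ (1, Z[, X]);
stage-2 normal regression of Y on (1, Ĉ0, Ĉ1[, X]).  The stage-2 design is
exactly rank-deficient (the predictions live in span{1, Z, X}); the normal
prior on βC0 — the effect of standard treatment versus nothing, the quantity
historical evidence informs — supplies the missing direction.  Flat priors on
the other coefficients, Jeffreys 1/σ² on the residual variance.  X enters
both stages additively so all analyses adjust for the observed covariate.

Sampling is Gibbs: β | σ² is multivariate normal with precision
Q'Q/σ² + P (P the prior precision, non-zero only for βC0) and σ² | β is
inverse-gamma.  In the default **joint** variant every sweep first draws the
stage-1 coefficients and variances from their exact normal-inverse-gamma
posteriors and rebuilds the predictions, so first-stage uncertainty
propagates (a cut/two-stage posterior); the **plug-in** variant fixes the
predictions at their least-squares values.  Defaults: joint, 4 chains × 2500
draws after 500 warm-up for single fits; inside replication grids the
plug-in variant with 2 chains × 1000 draws after 400 warm-up (the
first-stage uncertainty ignored there is small for a binary instrument, and
the two variants agree on scenario A1 within Monte-Carlo error — tested).
Convergence is monitored by split-R̂ on the contrast (threshold 1.01, via
arviz); non-convergence flags the result rather than raising.  The estimate
is the posterior mean of βC1 − βC0, the standard error its posterior SD, and
the interval the equal-tailed credible interval.

The prior grid crosses centering (at the generating βC0, or displaced by
+0.5 = 0.5σ) with precision (sd 1 "precise", sd 10 "vague").  A useful
closed form for intuition (and a test oracle): as the prior sd → 0 at mean
b0, the posterior contrast centres on (Ȳ1 − Ȳ0 + b0·p̂0)/p̂1 − b0, so the
bias from mis-centering is proportional to (p̂0 − p̂1)/p̂1 — zero when the
arm compliance rates coincide.

## Simulation engine

Replication i of a study uses the deterministic substream
`SeedSequence(master_seed, spawn_key=(i,))`, split between data generation
and the sampler, so any record is reproducible independently of `n_reps` or
the estimator grid.  Failures (e.g. 2SLS identifiability errors) are recorded
with their reason and never abort a study.  Reporting filters *mark* rather
than delete: interaction-IV replications with model SE above 10× the
empirical ITT SE of the scenario, and IPW replications with perfect-prediction
flags; summaries are available both filtered (the reported convention) and
unfiltered.  Summaries report mean estimate, bias, empirical SE (SD of
estimates), mean model SE and its relative error, the NI declaration rate
(type-I error at the boundary null), and the precision increase of ITT,
100·((SE_alt/SE_ITT)² − 1), with Monte-Carlo standard errors (empirical
SE/√n for means, binomial for rates).

## What the synthetic data do and do not emulate

The generator reproduces the structural features the estimators react to:
all-or-nothing compliance driven by observed/unobserved covariates with
arm-specific associations, confounding of compliance and outcome, effect
heterogeneity, and the boundary-null configuration.  It does not emulate
time-varying or partial compliance (the setting where per-time-point
weighting would be needed), non-normal or heteroscedastic outcomes, missing
data, multiple or continuous covariates, or block randomization.  Passing
tests therefore certify the estimators' behaviour under the stated generative
model, not under arbitrary real-trial data.

## Problem sizes and tolerances

Replicated checks use 2000 replications for the frequentist estimators
(Monte-Carlo SE of a 2.5% rate ≈ 0.35 points) and 500–1000 for the Bayesian
IV, with all mean/rate assertions at 3 Monte-Carlo SEs; directional
failure-mode assertions (a bias or inflation exceeding 3 MC-SEs) only lose
power at smaller replication counts, never gain it.  Oracle equivalences
(moment-equation 2SLS, hand-computed IPW weights, the degenerate-prior
closed form) are exact to 1e−8–1e−10.

## Known limitations and open choices

* The ITT anti-conservatism demonstration (10% trial-specific non-compliance,
  truth on the margin) uses n = 1000: at n = 100 the inflation is only
  ≈1.4-fold because the margin is wide relative to the sampling error.
* Under unmeasured confounding with the *same* association in both arms and
  only an arm-level shift (scenario A4a), the complier-selection bias of
  PP/IPW is tiny (≈0.01); the clear failure mode needs arm-opposite
  selection (A4b), which is what the failure-direction tests use.
* The Bayesian IV's posterior SD modestly exceeds its empirical SE at n=100
  (the prior contributes width along the unidentified direction), so its
  boundary-null declaration rate runs slightly below the nominal 2.5%
  (≈1.7% on scenario A1); the joint variant is a little more conservative
  than the plug-in.
* IPW standard errors ignore the estimation of the weights (the sandwich
  treats them as fixed), matching common software defaults.
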