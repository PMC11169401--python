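# Methods

This note documents the models, the defaults and the reasoning behind
the design choices in `batdisturb`, in the spirit of a statistical
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A *night* is labelled by the calendar date of its evening (the sunset
side). Hibernacula surveys end hours before dark, so "the night
following a survey" is the night whose label equals the survey date.
A winter *season* is labelled `YYYY/YYYY` by its spanning years;
November–December nights belong to the winter of their own year,
January–March nights to the winter that began the previous year.
Detector-off nights are carried in the activity tables with
`observed = false` and no count; they are excluded from the likelihood,
never imputed, and a survey whose following night was a detector-off
night is dropped from the logistic stage with a logged warning.

The *disturbance factor* is DF = (number of researchers) × (total
minutes the crew spent in the cave). It is stored redundantly in the
survey table and re-validated on read: a record whose factor does not
equal the product exactly is flagged.

## Seasonal activity smooth

Per cave-season-species series, nightly counts are fitted with

y_i ~ Poisson(mu_i),  log mu_i = beta_0 + f(d_i),

where d_i is day-of-season. The smooth f is a low-rank penalized
spline: a cubic B-spline basis of dimension k (default 10, reduced with
a warning when a series has fewer distinct nights; fewer than four
distinct nights is an error) on *uniform* knots, with a second-order
difference penalty on the coefficients and the usual sum-to-zero
centering constraint absorbed by a QR null-space transform so the
smooth is identifiable next to the intercept. Uniform knots make the
penalty nullspace contain exactly the functions linear in date, so the
smoothing parameter interpolates between an unpenalized spline fit and
a log-linear trend. This construction was chosen over an exact
thin-plate eigenbasis because it has the same nullspace and penalty
order, is a few dozen lines of transparent linear algebra, and its
limits (lambda = 0, lambda -> infinity) admit closed-form oracles used
in the tests.

Fitting is penalized IRLS to a relative penalized-deviance change below
1e-8 (at most 100 iterations; non-convergence is flagged on the fit,
not raised). The smoothing parameter is selected by generalized
cross-validation on the deviance scale,

GCV(lambda) = n D(lambda) / (n − edf(lambda))²,

over a 41-point grid in log10(lambda) from −4 to 6; edf is the trace of
the influence matrix. A fixed lambda can be supplied instead. An
all-zero series yields a degenerate intercept-only fit with a warning.

Overdispersion is measured by the Pearson estimate
phi = Σ (y_i − mu_i)²/mu_i / (n − edf). Each series is fitted as
Poisson first; when phi exceeds a threshold (default 1.5 — the counts
of interest are typically overdispersed well beyond that, and a
configurable cutoff is exposed because no universal value exists) the
fit is reinterpreted as quasipoisson: identical coefficients and fitted
means, standard errors inflated by sqrt(phi).

Standard errors of the fitted linear predictor use the Bayesian
posterior covariance of a penalized fit,
V_beta = phi (XᵀWX + lambda S)⁻¹, the standard choice for penalized
smooths because it accounts for smoothing bias.

## Exceedance classification

The classifier consumes the final-iteration IRLS working residuals
weighted by the square root of the IRLS weights,
r_i = sqrt(w_i)(z_i − eta_i), which for the Poisson/log model equal the
Pearson residuals (y_i − mu_i)/sqrt(mu_i) and have approximately
constant variance phi under a correct model.

A night is flagged when r_i > m × SE_env,i with multiplier m = 2 by
default, one-sided on the high side only (low activity after a survey
is not evidence of disturbance). The envelope SE is the
prediction-scale standard error on the weighted working scale,

SE_env,i = sqrt(phi_eff + w_i se_fit,i²),

combining the scatter of a single night about the true curve (phi_eff =
1 for Poisson, the Pearson phi for quasipoisson) with the uncertainty
of the fitted curve itself. This choice matters: against the SE of the
*fitted curve alone* the envelope narrows as the series lengthens and
an arbitrarily large fraction of ordinary nights would be flagged,
whereas the prediction-scale envelope gives a stable one-sided
exceedance rate of about 2.3% under a correct model at m = 2 — the
behaviour a disturbance screen needs. Because residual and envelope
carry the same sqrt(w_i) factor, the classification is identical on the
weighted and unweighted working scales. A response-scale variant is
deliberately not offered; the working scale is where the residuals have
constant variance.

Nights that are unobserved or outside the fitted season receive an
explicit *unassessable* status, never a 0, so absence of evidence is
not recorded as evidence of absence.

## Logistic disturbance model

One survey contributes one observation per species. Candidate
covariates measured on the survey day (cave length, bats counted,
cluster counts and sizes) are screened with Pearson correlation against
the protected disturbance factor; any candidate with two-sided p ≤ 0.05
is excluded in its favour. This reflects a structural confound — larger
caves hold more bats and take bigger crews longer to search — that
would otherwise split the disturbance signal across collinear terms.

The remaining model set is all subsets of {DF, temperature, wind} plus
the intercept-only model (eight models). Each is fitted by
Newton-Raphson with step halving (tolerance 1e-8 on the log-likelihood,
50 iterations); a rank-deficient design raises an error naming the
collinear terms, and complete or quasi-complete separation — a real
hazard with few events — is detected from diverging linear predictors
that perfectly split the outcomes, and flagged on the fit rather than
silently returned. Models are ranked by AIC = 2k − 2 logL with Akaike
weights exp(−Δ_i/2)/Σ exp(−Δ_j/2); AIC rather than AICc is the default
to match standard practice in this literature, with AICc available
(`criterion="aicc"`). Ties at equal AIC rank the model with fewer
parameters first, then lexicographically.

Term importance is the drop-in-deviance likelihood-ratio test
(chi-square = deviance(reduced) − deviance(full), 1 d.f. per term);
a Wald variant is available. Classification efficacy is the rank-based
(Mann–Whitney) AUC with ties counted half; it is undefined (explicit
error) when only one outcome class is present.

Predictions are the inverse logit of the linear predictor; the
uncertainty band is eta ± b·SE(eta) transformed through the inverse
logit (delta method on the linear-predictor scale), which keeps bounds
inside (0, 1). The planning grid evaluates the fitted model over a
crew-size × minutes lattice via DF = product; when the DF coefficient
is positive the grid is monotone non-decreasing in both directions.

## Synthetic generator

The generator emulates the study conditions the pipeline targets: nine
caves monitored over winters (November–March), one survey per
cave-season, crews of 3–4 researchers spending 19–175 minutes
underground, and a mean overnight temperature of −5.4 °C with a
seasonal trough mid-winter and AR(1) night-to-night noise (sd 3 °C,
lag-1 correlation 0.7 — values chosen to look like high-desert winter
records). Defaults:

* baseline activity exp(log 3) = 3 call files/night at mid-season,
  seasonal log-amplitude 1.0 (activity dips mid-winter), temperature
  effect +0.08 per °C on the log rate — warm nights see more natural
  flight, which is exactly the confound the screening and modelling
  stages must cope with, since temperature also enters the disturbance
  law;
* negative-binomial counts with shape theta = 1 (variance mu + mu²),
  so the Poisson branch of the activity model is genuinely
  overdispersed and the quasipoisson switch is exercised; theta is
  configurable up to the Poisson limit;
* detector-off probability 0.05 per night;
* disturbance law with the published coefficients (−3.817, 0.013,
  0.472) as the default truth, so recovery tests target the same
  numbers the analysis is meant to reproduce;
* on a latent response, the count of the single night following the
  survey is redrawn with its expected value multiplied by 10 (the
  spike magnitude is a free parameter, not an estimate — real
  disturbance magnitudes are poorly characterized); survey minutes
  scale with cave length, reproducing the cave-size confound.

What the generator does **not** emulate: within-cave flight that never
passes the detector (so measured activity understates disturbance),
torpor-bout physiology, multi-night disturbance persistence,
detector sensitivity drift, and species interactions. Passing tests
therefore demonstrate that the pipeline recovers the generating law
under its own assumptions — not that those assumptions exhaust real
cave acoustics.

## Numerical choices and degenerate inputs

* IRLS starts from mu = (y + mean(y) + 0.1)/2; linear predictors are
  clipped at ±30 before exponentiation.
* Penalized normal equations are solved by Cholesky with an
  lstsq fallback for near-singular systems.
* Logistic probabilities are computed with `scipy.special.expit`;
  all-one or all-zero outcome vectors fit to the boundary and are
  flagged (`boundary=True`) rather than raised.
* Zero-variance screening candidates are excluded with reason
  "degenerate"; Pearson screening requires at least 3 complete pairs.
* Deterministic runs: the generator derives independent sub-streams
  per component from a single seed, and the pipeline writes a config
  digest (output paths excluded) into the report header so identical
  analyses are recognizably identical.

## Problem sizes used in the test suite

Simulation-backed guarantees run at sizes chosen to bound Monte-Carlo
error while keeping the suite quick: 200 simulated undisturbed
cave-seasons of ~140 nights for the null flag rate, 200 spiked series
for detection power, 200 datasets of 400 surveys for logistic
parameter recovery, and 10,000 draws where a closed-form mean is
checked. The published-number checks (prediction evaluations, survey
table aggregates, Akaike-weight arithmetic) are exact desk-scale
computations.

## Known limitations

* The activity smooth is a single smooth of date; it does not model
  weather covariates or autocorrelation in the counts, so weather-driven
  activity bursts can inflate the exceedance rate on real data.
* With 17 surveys and 3 events, the logistic stage is at the edge of
  what maximum likelihood supports; separation is flagged but not
  penalized away (no Firth correction), and absolute AIC values for
  such small samples depend on the observational unit.
* The survey-night classification window is a single night; bats
  aroused late may fly on the second night and be missed.
* Quasipoisson inference scales SEs by sqrt(phi) but keeps the Poisson
  point estimates; strongly clumped counts may deserve a full
  negative-binomial likelihood.
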