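# Methods

## Models

All ten model kinds are fit by direct maximization of the observed-data
log-likelihood with analytic gradients (no EM for the mixtures — a single
code path makes the sandwich variance over the full parameter vector
straightforward, which the ZIRP analysis needs).  Count parts use a log
link, binary/inflation parts a logit link.

* **LR** — logistic regression on the dichotomized outcome `1{y > 0}`.
* **PR / RP** — Poisson regression; RP is the same fit with the
  Huber–White sandwich covariance `A⁻¹BA⁻¹` (`A` = observed information
  from a central-difference Hessian of the analytic score, `B` = outer
  product of per-subject scores).
* **NB** — NB2 parameterization, variance `μ + αμ²`.  The dispersion is
  estimated on the log scale to enforce `α ≥ 0`; a fit pinned below
  `1e-8` is reported as `α = 0` with a warning.
* **GP** — restricted generalized Poisson (Consul–Famoye GP-1),
  mean-parameterized with `θ = μ(1 − δ)`, admissible region
  `max(−1, −μ/4) < δ < 1`.  Chosen over other GP variants because it
  accommodates both under- and overdispersion, which the selection logic
  needs; the pmf's finite-support truncation for `δ < 0` is the standard
  caveat of this form and is handled by assigning zero mass to invalid
  terms.
* **ZIP / ZIRP / ZINB / ZIGP** — two-part mixtures
  `P(0) = π + (1−π)f(0)`, `P(y) = (1−π)f(y)`.  The inflation part models
  the odds of an *excess* zero; since odds ratios are symmetric, the
  inverse of an inflation OR reads as the effect on having detectable
  polyps.  Count and inflation design matrices may differ (observational
  analyses sometimes adjust a covariate in one part only).
* **ZHP / ZHNB** — hurdle models.  The likelihood factorizes exactly into
  a logistic part on `1{y > 0}` (identical, coefficient for coefficient,
  to a plain logistic regression) and a zero-truncated count part on the
  positives; the total log-likelihood is their exact sum and the joint
  covariance is block-diagonal.

## Numerical choices

Everything is evaluated in log space: zero-heavy data make `f(0)` terms
dominate, and mixture zeros are combined with `logaddexp`.  Two NB2
stability details matter near the Poisson limit `α → 0`: the log-pmf is
rewritten with exact `log1p` sums (`lnΓ(y+r) − lnΓ(r) − y·ln(r+μ) =
Σ_{j<y} log1p((j−μ)/(r+μ))` with `r = 1/α`), and the dispersion score uses
the finite harmonic sum for `ψ(y+r) − ψ(r)` plus a series for the zero
term — the naive gammaln/digamma forms lose all significant digits once
amplified by `r²`, which stalls any gradient-based optimizer at the
boundary.

Optimization is BFGS on the analytic gradient (target gradient norm 1e-8,
max 500 iterations), followed if needed by Newton polishing with
ridge-regularized numerical Hessians and, as a last resort, Nelder–Mead.
A polish step is also accepted when it shrinks the gradient norm while the
objective is unchanged to machine precision (the flat-boundary regime).  A
fit is declared converged only when the score max-norm is below 1e-6.

Starting values: Poisson fits seed NB/GP (dispersion from moments); the
mixture count part is seeded by a Poisson fit to the positive counts and
the inflation intercept by the logit of the observed excess-zero fraction
relative to the Poisson prediction (floored at 0.05).  Degenerate cases
are handled explicitly: with no zeros, or when the inflation intercept is
driven to −∞ on data without excess zeros, the mixture collapses onto the
plain count GLM (returned as such with a warning, inflation intercept
pinned at −20); a genuinely diverging inflation part (|b| > 15 with the
likelihood above the GLM's) raises an instability error recommending a
hurdle model.  Perfect separation in any logistic part is detected from
the coefficient magnitude (the gradient underflows to zero under
separation, so convergence flags alone cannot catch it).

## Diagnostics and selection

* **Score test for zero inflation** against the fitted Poisson:
  `S = [Σ(1{y=0} − p₀)/p₀]² / [Σ(1−p₀)/p₀ − nȳ]`, `p₀ = e^{−μ̂}`, referred
  to χ²(1).  The statistic is reported on the χ² scale; values in the
  hundreds on real polyp data are only coherent as χ², not as a z-value.
* **Bias-corrected Vuong test**: per-subject log-likelihood differences
  with the AIC penalty difference spread over subjects (default, BIC
  optional); positive Z favors the inflated model, one-sided p.
* **Excess-zero removal** is deterministic: `round(Σπ̂ᵢ)` observed zeros
  with the highest structural posterior `π̂ᵢ/P̂(Y=0)` are dropped, ties by
  record order.  Determinism was preferred over random thinning for
  reproducibility of the downstream dispersion tests.
* **Dispersion tests** on the reduced data: the auxiliary regression of
  `((y−μ̂)² − y)/μ̂` on `μ̂` (slope t-test, sign gives direction) and the
  NB2 boundary likelihood-ratio test `2(LL_NB − LL_PR)` against the
  ½χ²(0) + ½χ²(1) mixture.
* **Goodness of fit**: observed vs expected counts over cells
  `0, …, 5, 6+` (expected from per-subject model probabilities; sparse
  cells with expected < 1 merged upward).  The degrees of freedom are
  `cells − 1 − df_adjust` with `df_adjust = 2` by default; the adjustment
  for estimated parameters in this setting has no universally agreed
  value, so it is configurable and always reported.
* **Flowchart**: no excess zeros → single-distribution family by
  dispersion; excess zeros → the declared zero *type* picks hurdle
  (structural only) vs inflated (mixed); residual overdispersion after
  removal picks NB-based members, otherwise the Poisson member with
  robust variance; BIC and GOF break remaining ties.  The zero type is a
  substantive judgment about the data-generating process and is required
  as input, never inferred from the data.

Counts can be topcoded (default cell boundary 6) to mirror primary
analyses that merge six or more polyps; topcoding is off by default for
simulation work.

## Marginal standardization

For any fitted model, `P(Y > 0)` is predicted for every subject with the
group set to 1, then 0; the averages give the marginal PDR difference and
marginal odds ratio.  CIs are percentile bootstrap (B = 1000 by default,
seeded, subjects resampled and the model refit) — a delta method across
two-part models is fragile, and the bootstrap is exactly reproducible
under a fixed seed.  Note that a "detection rate" column in a published
comparison may equal the mean of `P(Y = 0)`; this package reports mean
`P(Y > 0)` and exposes the complement explicitly.

## Synthetic data

The generator multiplies a Bernoulli structural-zero indicator by a count
draw: `y = (1 − structural)·count`, with `group ~ Bernoulli(0.5)`,
`structural ~ Bernoulli(logit⁻¹(b₀ + b_g·group))` and
`log μ = β₀ + β·group (+ γ·confounder)`.  TZ (marginal structural-zero
rate) and SZ (marginal count-component zero mass) are the primitive
parameters; `β₀` is root-found so that the covariate-law average of
`f(0|x)` equals SZ (Gauss–Hermite quadrature over the confounder), and
the implied overall zero fraction is `TZ + (1−TZ)·SZ`.

The three reference scenarios (N = 425, β = 0.40) are: (1) TZ = 52.5%,
SZ = 18%, Poisson; (2) TZ = 16%, SZ = 1%, Poisson; (3) TZ = 52.6%,
SZ = 28.9%, NB2 with α = 0.50 plus a standard-normal confounder with
coefficient 0.2 on the count log-mean and 0 on inflation (the confounder
coefficients are exposed configuration, chosen as plausible defaults for
an observational design, not calibrated to anything).  The group
coefficient on the inflation logit defaults to 0.  Under that default the
*single-distribution* models are close to unbiased for β — their large
biases in published comparisons require a dependence between the
inflation part and the group that is not part of this generator's stated
design — so only the inflated/hurdle-model rows are meaningful
reproduction targets, and the Monte Carlo engine's headline checks use
those.

What the generator does not emulate: covariate-dependent inflation beyond
a single group term, correlated covariates, measurement error in counts,
and informative missingness.  Passing simulation checks therefore
demonstrate estimator correctness under the stated mixture design, not
robustness to those real-data features.

## Monte Carlo evaluation

Per replication: generate, fit each requested model (group in the count
part; for two-part models also in the zero part), record the count-part
group coefficient and its 95% Wald CI.  Summaries: bias `mean(β̂) − β`,
relative bias `bias/β`, mean CI width, and coverage.  Replication seeds
spawn deterministically from the master seed (`SeedSequence`), so results
are bit-identical across reruns.  Failed fits are dropped and counted
(never imputed); a model failing in more than 20% of replications is
flagged unreliable.  The reference evaluation uses 1000 replications
(~40 s on one CPU); the test suite uses a 200-replication smoke version
with proportionally wider tolerances.

## Known limitations

* ZINB/ZIGP identifiability is weak when structural zeros and count
  overdispersion both generate zeros at N in the hundreds; interval
  coverage for ZINB in the misspecification scenario runs a few points
  below nominal and inflation-part estimates can be unstable — consistent
  with the general advice to prefer ZIRP or a hurdle NB there.
* The GP density's truncation for `δ < 0` means its pmf sums to slightly
  less than 1 for strong underdispersion; normalization checks are exact
  for `δ ≥ 0`.
* Offsets/exposure terms and clustered/repeated-measures designs are out
  of scope; QP scale-factor inference is subsumed by the sandwich-variance
  mode.
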