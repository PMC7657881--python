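# Methods

## The experiment being modelled

Third-party listeners judge whether two people heard vocalizing together
are friends or strangers.  The design is fully crossed within
participant: familiarity of the recorded dyad (friends / strangers) ×
vocalization mode (colaughter / cospeech) × playback speed (original /
sped-up), with 108 participants, 24 conversations contributing the first
and last qualifying occurrence of each mode (96 clips), and two
counterbalanced lists deciding which half of the clips each participant
hears sped-up.  Every participant hears every clip exactly once, in
exactly one speed version; responses are binary (1 = "friends").  The
behavioural responses themselves are not deposited, so the package
treats a generative simulator of this design as first-class and
validates the analysis by parameter recovery.

## Generative model and analysis models

A trial's response is Bernoulli(Φ(η)) with

η = x'(β + u_j) + s_i,

where x is the 0/1 design-code vector over the eight terms (intercept,
familiarity, talk, speed, familiarity:speed, familiarity:talk,
talk:speed, familiarity:talk:speed; reference levels strangers,
cospeech, original), u_j ~ MVN(0, diag(σ_p)·Ω·diag(σ_p)) is participant
j's deviation vector, and s_i ~ N(0, σ_s) is the stimulus intercept.
Five nested models are fit: Model 0 (intercept only), Model 1
(+familiarity), Model 2 (talk terms), Model 3 (speed terms, no talk),
Model 4 (all eight).  In every model all fixed terms vary by
participant and the intercept varies by stimulus.

SDT reading: for each mode × speed cell, the criterion is the cell's
linear predictor for stranger stimuli and the sensitivity (d′) is the
friends-minus-strangers difference; both are fixed linear combinations
of β documented in `sdt.cell_combination`.  Percent-scale views are
100·Φ(c) and 100·(Φ(c+d′) − Φ(c)).

## Choices the design left open

These points are implementation decisions of this package, exposed in
configuration so alternatives remain testable:

- **Predictor coding**: 0/1 indicators with reference levels
  strangers/cospeech/original.  This makes every condition quantity a
  simple sum of coefficients and lets the reported condition table be
  inverted exactly into the eight β's (`study.betas_from_condition_z`).
- **List assignment**: participants alternate between the two lists by
  index; presentation order is an independent seeded permutation per
  participant.  With a single list no counterbalancing is possible and
  all clips play at original speed.
- **Random-effect family**: multivariate normal (the conventional
  reading of correlated varying slopes).
- **Stimulus identity**: the two speed versions of a clip share one
  stimulus intercept (stimulus = clip, 96 intercepts), matching a model
  with 96 stimulus units.
- **Percent-scale convention**: the condition table applies the
  transform at the posterior-mean z (transform-of-mean).  This choice
  reproduces every printed percent/z pair exactly after rounding;
  mean-of-transform is also provided and agrees within about a point
  for |z| ≤ 1.
- **Liking ratings** are generated only as a monotone noisy map of
  Φ(η) onto 1–7 for I/O testing and are never modelled.

## Priors

Fixed effects of the manipulations: N(0, 0.3), selected by
prior-predictive screening over scales {1, 0.5, 0.3, 0.1} — the
criterion is a broad but non-extreme distribution of the overall
"friends" rate (probability of a rate outside [0.05, 0.95] is monotone
in the scale and small at 0.3).  The screening applies the candidate
scale to the whole fixed-effect vector; unit-level variance can
optionally be folded in through the probit-normal identity
Φ(η/√(1+v)).  Choices not pinned down elsewhere: the intercept prior is
N(0, 1) (a bias as extreme as ±1 z is implausible but not excluded);
random-effect sds are half-normal(0.3); the participant correlation
matrix is LKJ with concentration 2.  All four scales are fields of
`PriorSpec`.

## Posterior computation

Sampling is by an in-package dynamic Hamiltonian Monte Carlo sampler
(No-U-Turn termination, multinomial state selection), written against an
analytic-gradient log-posterior:

- Non-centered parameterization throughout (u_j = diag(σ_p)·L·z_j,
  s = σ_s·v), chosen because the priors favour small group sds.
- Positive scales sampled on the log scale; the correlation Cholesky
  factor L mapped from unconstrained space via tanh partial
  correlations and stick-breaking on the sphere, with the LKJ density
  and transform Jacobian in the target.  The transform's gradient is
  exact and verified against finite differences; the implied LKJ(2)
  marginal is verified by its closed-form second moment at K = 2.
- Warmup: dual averaging of the step size toward the target acceptance
  statistic, with expanding diagonal mass-matrix windows (Stan-style
  schedule: 15% step-size-only, doubling covariance windows, final 10%
  step-size-only).
- Divergences are energy errors above 1000 nats; they are counted,
  reported, and surfaced as a warning.
- Default configuration mirrors the original analysis: 2 chains × 3000
  iterations (half warmup — whether the original 3000 included warmup
  is ambiguous, and `warmup_fraction` exposes both readings), target
  acceptance 0.99, trajectory depth cap 20.
- A **reduced profile** (2 × 600 iterations, target acceptance 0.9,
  depth cap 10) is the package's own fast profile for simulation
  studies and examples; problem sizes for those are 24 participants ×
  48 stimuli.
- An adaptive random-walk Metropolis (within blocks) fallback needs
  only log-density evaluations; it is cross-checked against the HMC
  sampler in distribution on Gaussian targets and used to sample the
  correlation prior in tests.

Diagnostics follow the conventional quality checks: no divergences;
split-Rhat within [0.99, 1.01] and effective samples above 200
(computed via arviz); and a prior-vs-posterior learning check comparing
interquartile ranges per fixed effect.  Reduced-profile runs routinely
flag ESS — chains of 300 kept draws cannot clear 200 effective samples
for slow-mixing scale parameters — which is reported honestly rather
than suppressed.

## Model comparison

PSIS-LOO is implemented in-package: per-trial importance ratios 1/p(y_i
| θ_s); tail = min(0.2·S, 3·√S) largest ratios replaced by expected
order statistics of a generalized Pareto distribution fitted to the
exceedances (profile-likelihood/quantile estimator with a weak prior
toward k = 1/2; a method-of-moments fallback is cross-checked); weights
capped at the largest raw ratio and self-normalized; LOOIC = −2·elpd.
Trials with tail shape k > 0.7 are flagged.  The implementation is
checked three ways: against exact leave-one-out by refitting (1-D
quadrature) on an 8-trial toy posterior (agreement within 0.1 elpd),
against arviz's independent implementation on identical log-likelihood
matrices, and against simulations with known Pareto tail index.
Constant importance ratios return uniform weights with k = −∞ as an
explicit sentinel.  No LOOIC values are asserted against the original
analysis because its comparison table is not available; only the
ranking behaviour is validated on simulated data.

## ROC and AUC

Scores are posterior probabilities of "friends".  Curves are traced by
threshold sweep (default 1001 evenly spaced thresholds; exhaustive
observed-score thresholds give exact agreement with the rank AUC).  AUC
uses the Mann–Whitney rank identity with half-credit ties — exact, and
verified against brute-force pair enumeration and scikit-learn.  AUC
intervals are computed per posterior draw (the plotted curves use
posterior-mean scores; the intervals require draws, mirroring how the
two are reported).  Internally curves are FPR/TPR; the writer offers
the specificity x-axis convention ("strangers correctly identified") as
an option.  Prediction for units absent from the fit is refused unless
marginalization over new units is requested (probit-normal identity).

## What the simulator does and does not emulate

The simulator reproduces the trial structure (counts, counterbalancing,
factor crossing), the probit response process, participant and stimulus
heterogeneity, and ground-truth effects set to the condition-level
estimates of the original experiment (criterion −0.22, −0.01, −0.03,
0.16; sensitivity 0.33, 0.22, 0.70, 0.69 on z).  Defaults chosen where
no value is reported: participant sds (0.3, 0.3, 0.15, 0.15, 0.1, 0.1,
0.1, 0.1) — listener bias and ability vary more than their higher-order
modulations; stimulus-intercept sd 0.4 — individual clips plausibly
differ more than conditions do; identity participant correlation (the
model estimates correlations, the generator stays neutral about them).
It does not emulate: sequential/order effects, response omissions,
listener fatigue, acoustic properties of the clips, or any dependence
between the liking rating and the judgement beyond a shared Φ(η).
Passing recovery therefore shows the inference machinery is correct
for data generated by the model class, not that the model class is
true of real listeners.

## Numerical notes

- Likelihood uses the stable normal log-CDF; finite for |η| beyond 30.
  The gradient's inverse-Mills ratios are computed in log space.
- Quantile-type summaries: 2.5/97.5 posterior percentiles; credibility
  of sign is the share of draws on the side of the posterior mean
  (reported as 100 when all draws agree — no continuity correction).
- Display rounding for condition tables: z to 2 decimals, percent to
  integers; unrounded values are retained.
- Degenerate inputs fail loudly: single-valued responses, single-class
  ROC subsets, empty prior grids, mismatched units and uneven list
  splits all raise typed errors naming the problem.
- Determinism: every stage seeds from a single master seed through
  SHA-256-derived per-stage seeds (< 2³¹); identical configuration
  gives byte-identical simulated tables and identical draws for a
  fixed sampler version.

## Known limitations

- One reported quantity is internally inconsistent in the original
  text: the criterion difference between colaughter and cospeech is
  printed as −0.19 with interval (0.07, 0.32), which cannot all be
  right (the condition means imply +0.19).  The package computes the
  contrast from the condition means and does not assert the printed
  sign; the discrepancy is deliberately not "corrected" silently.
- Whether the reported AUCs used all trials or balanced per-condition
  subsets is not stated; both subsetting modes are available.
- The sampler is pure NumPy: correct and exact-gradient, but roughly an
  order of magnitude slower than compiled samplers; full-scale fits
  (10 368 trials, 2 × 3000 iterations) take on the order of an hour.
- No logit-link variants, ordinal models for liking, WAIC/k-fold CV,
  model stacking, partial AUC, or binormal ROC smoothing.
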