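# Methods

`awarekit` implements a model-based analysis chain for masked-priming
experiments in which every trial yields a speeded probe response (RT), a
forced-choice report of the masked prime's shape, and a PAS visibility
rating, with prime-absent catch trials interleaved.  This note documents the
models, the defaults and why, the numerical choices, and what the synthetic
data can and cannot show.

## Experiment simulator

The generator is the exact generative counterpart of the models fitted
downstream, so every estimator can be validated by parameter recovery.

**Design.** Blocks of 320 trials with 20% (64) prime-absent catch trials;
present trials split equally between square and diamond primes and, within
shape, between congruent and incongruent prime-probe pairings.  Probe
identity is balanced orthogonally to prime identity (the balance is
configurable: real designs do not always state it).  Display timings are
multiples of the 75-Hz frame (13.33 ms).  The two backward-mask settings -
mask immediately for 5 frames, or a 1-frame blank then a 4-frame mask -
both put the probe 8 frames (106.7 ms, conventionally written 107 ms) after
prime onset; `soa_ms` checks this arithmetic.

**Percepts.** Each trial draws a bivariate Gaussian percept over (identity
evidence, awareness evidence) from its stimulus class; the absent class is
N((0,0), I).  The prime 2AFC choice thresholds the identity axis; the PAS
rating bins the awareness axis at three ordered cutpoints.  Defaults place
the present classes at identity +/-0.25 and awareness 0.5 (in absent-class
SD units): weak, near-threshold visibility, the regime the paradigm is
designed for.  A per-block attention multiplier scales present-class means
(default 1.25 in the visibility block, where the prime is the task);
means - not variances - because that is the simplest manipulation that
moves d' monotonically.  Participant heterogeneity enters as a Normal(0,
0.3) offset on present-class awareness means, giving the regression a true
between-subject spread.

**RTs.** Lognormal around a per-block base (sigma_log 0.15, so ~80 ms SD at
520 ms), plus, on incongruent trials, a congruency cost alpha + beta *
(awareness evidence - mean present awareness).  `alpha` (default 10 ms,
the order of magnitude of reported masked-priming costs) is the
awareness-independent effect; `beta` makes priming awareness-driven.
Probe errors are an independent Bernoulli flip (3%).

**Seeding.** One master seed; participant substreams are spawned by
counter, so any participant can be regenerated in isolation and cohorts can
be extended without reshuffling existing participants.

**What it does not emulate:** sequential effects, practice/fatigue drift,
RT-accuracy tradeoffs, response omissions, non-Gaussian percept noise, and
PAS criterion drift over time.  Passing recovery tests therefore show the
estimators are correct under their own assumptions, not that the
assumptions hold for any particular lab's data.

## Trial and participant filtering

For RT analyses: drop probe-incorrect trials, then RTs outside [200, 2000]
ms (boundaries kept: the rule removes strictly below/above), then a single
mean +/- 2 SD pass computed per participant x block on the in-window
survivors.  The SD pass is deliberately not iterated and not computed per
condition.  When PAS-1 selection applies (multiple-task block), it happens
after trimming, so the SD pass sees the participant's full in-window RT
distribution; a switch exposes the other order.  Participants are flagged
for exclusion when probe accuracy in the multiple-task block is strictly
below 75%, or PAS-4 reports exceed 10% of catch trials in the multiple-task
or visibility block; a flag whose defining block is absent is reported as
missing, never as false.

## SDT sensitivity measures

Both awareness measures are mapped to the same yes/no convention so they
can be compared on one metric: d' = z(H) - z(F), c = -(z(H) + z(F))/2.
Objective: square primes as signal, "square" responses as yes, catch trials
excluded.  Subjective: prime-present trials as signal, PAS >= 2 as yes,
catch trials as noise.  No sqrt(2) 2AFC correction is applied - the
discrimination is treated as signal-vs-noise over the two prime
identities, which keeps d'_obj and d'_subj on a common scale.  The
log-linear correction (+0.5/+1) is applied unconditionally so the estimate
is finite and continuous in the counts; the uncorrected value is kept for
audit.  Group summaries average per-participant d' values; they are never
the d' of pooled counts.

## Default Bayes factors

*t-tests.*  JZS: Cauchy(0, r) prior on the standardized effect, r =
sqrt(2)/2 by default, two-sided by default (one-sided is a flag).  The
two-sided BF integrates the scaled-g representation (elementary integrand,
stable at any n, relative quadrature error ~1e-8, reported); the one-sided
BF integrates the positive half-Cauchy against the noncentral-t density.
A paired test is literally the one-sample test on the differences.

*Correlations.*  Uniform prior on rho (stretched-beta kappa = 1); the
rho-likelihood is the exact sampling density of Pearson r (Gaussian
hypergeometric form), integrated by quadrature.

*2 x 2 repeated-measures ANOVA.*  Zero-sum +/-1/2 effect codes for the two
factors and their product, orthonormal contrasts for subjects; scaled-g
priors (one g per effect: fixed scale 0.5, subject scale 1.0).  Conditional
on g the marginal-likelihood ratio against the subject-only null is closed
form; the g's are integrated out by a Laplace approximation on the log
scale (deterministic, hence repeatable) with optional plain Monte-Carlo
refinement whose standard error is reported.  Model space: null(+subject),
+A, +B, +A+B, full.  Inclusion BFs use matched models: main effects compare
{A, A+B} against {null, B} (interaction model excluded); the interaction
compares full against A+B.  Calibration is by simulation: null data yield
median inclusion BFs below 1; a 5-SD planted effect yields BF > 100.

## Measurement-error regression (priming at zero awareness)

The dissociation logic needs the priming effect at exactly chance
awareness.  Regressing observed effects on observed accuracy (the naive
Greenwald-style estimate) is biased: binomial noise in the predictor
attenuates the slope, and when the cohort is on average above chance the
attenuation leaks into the intercept.  The generative correction models

    correct_i ~ Binomial(n_i, theta_i),  theta_i ~ Beta(m nu, (1-m) nu)
    effect_i ~ Normal(alpha + beta (theta_i - 1/2), sqrt(tau^2 + se_i^2))

with priors alpha ~ N(0, 50 ms), beta ~ N(0, 300 ms/unit), tau ~
half-N(0, 30 ms), m ~ Beta(2, 2), log nu ~ N(log 50, 1): weakly informative
on the RT scale and fully exposed in config, because Bayes factors depend
on them.  The centered predictor is theta - 1/2 (chance in the two-choice
task); a d'-scale predictor is available as a flag.

Sampling: affine-invariant ensemble MCMC (emcee; differential-evolution
moves, vectorized log-posterior), two independent 64-walker ensembles of
400 burn-in + 500 kept steps.  Walkers start overdispersed on each
parameter's own posterior scale - critical for the slope, whose posterior
can be as wide as its prior.  Convergence: rank-normalized split R-hat
across the independent ensembles for intercept, slope and log tau must be
below 1.01, or the chain length is doubled (twice) and then an explicit
error is raised; no silent results.

Savage-Dickey BF for intercept = 0: the prior ordinate is analytic; the
posterior ordinate uses, by default, a Rao-Blackwellized estimator - the
conditional posterior of alpha given (beta, tau, theta) is Gaussian in
closed form, so averaging its ordinate at zero over draws estimates the
marginal ordinate with far less error than any kernel smoother, including
in the far tail where kernel estimates are biased.  A Silverman-bandwidth
Gaussian KDE is computed alongside as a cross-check; the two agree within
10% whenever zero lies in the posterior bulk.

Calibration (run by the acceptance suite): over 100 cohorts of 24
participants x 256 awareness trials with a true 30-ms effect, the
posterior-mean intercept is unbiased to < 3 ms and the 95% credible
interval covers at its nominal rate; under purely awareness-driven priming
(alpha = 0, beta = 200 ms/unit, cohort mean awareness 0.55) the corrected
BF favors the null while the naive intercept is biased upward.

## GRT-wIND and sensitivity-vs-awareness curves

A two-dimensional Gaussian recognition model over (identity, awareness)
fitted jointly to the 2AFC-shape x PAS confusion counts, catch trials
included.  Identifiability anchor: absent class at mean (0,0) with unit
variances.  Individual differences: an attention scale kappa_i multiplying
present-class mean vectors - anchored to geometric mean 1 across the
cohort, so the global mean scale is estimated from everyone rather than
one reference participant - plus per-participant bounds: a vertical
identity criterion (identity decisional separability is always imposed)
and three ordered awareness cutpoints, which become parallel lines of
common per-participant slope when decisional separability on awareness is
relaxed.

The 16 model variants are the 2^4 combinations of: equal variances (all
classes at unit variance), perceptual separability (square and diamond
share the awareness marginal), perceptual independence (zero
identity-awareness correlation in every class), and decisional separability
(flat awareness bounds).  Constrained parameter sets nest in the full
model's.

**Likelihood.**  Every response cell is an exact bivariate-normal rectangle
probability: with a sloped bound, w = awareness - slope * identity is
jointly Gaussian with identity, so no 2-D quadrature is needed.  The
bivariate CDF is computed from Owen's T (vectorized, ~1e-14 accurate; the
engine is validated against 10^6-draw Monte Carlo).  Fitting is L-BFGS-B
on transformed parameters (log variances and kappas, atanh correlations,
ordered cutpoints via log gaps) with multi-start from moment-based initial
values, and a block-structured central-difference gradient batched into a
single vectorized probability call per iteration: global parameters
re-evaluate all participants, participant parameters only their own terms
(kappa parameters also touch the anchor participant).  AIC selects among
the 16 fits; ties break toward fewer parameters.

"Percent of observed response proportions accounted for" has no standard
definition; here it is 100 * (1 - MAD / mean observed proportion), with
MAD the mean absolute deviation between observed and predicted cell
proportions over participants x stimuli x 8 cells, and the raw MAD is
reported alongside.

**SvA curves.**  At the group level (kappa = 1): RLNA(a) is the absent
class's awareness density over the equal-weight square/diamond mixture
(equal weights because the design is equiprobable); d'_cond(a) is the
conditional identity separation over the pooled conditional SD, from the
Gaussian conditional formulas.  The ideal-observer criterion solves
RLNA = 1 by bracketed root-finding between the absent and highest present
awareness means; if the bracket has no sign change the criterion is
reported absent with a warning.  Grid: 200 points spanning [absent mean -
3 SD, max present mean + 3 max SD]; refining to 2000 points moves the
criterion by < 1e-3.  Confidence bands are a parametric bootstrap: simulate
counts from the fitted model at the observed per-condition totals, refit
the selected template only (warm-started), recompute both curves, take
pointwise 2.5/97.5 percentiles; more than 20% refit failures is an error.

**Calibration scales.**  Recovery and selection experiments use 20
participants x 320 trials (128 square / 128 diamond / 64 absent), 20
replicates, and 100-replicate bootstrap bands; these sizes keep the full
validation loop desk-sized while leaving clear statistical margins
(recovery tolerance 0.15 is ~3 posterior SDs of a class mean at this
scale).  Band coverage of the generating d'_cond curve is measured as the
mean covered fraction over several independent truth -> fit -> bootstrap
cycles, because a single cycle's covered fraction is nearly binary: the
true and fitted curves cross, so one parameter estimate landing a couple
of standard errors off removes a contiguous stretch of the curve from the
band.  Bands are reported for RLNA too, but coverage is only asserted for
the d' bands - the SvA curve's confidence interval lives on the d' axis.  A selection replicate counts as correct when AIC picks the
generating constraint set or a richer variant whose fitted parameters
satisfy those constraints within tolerance (variances within 0.12 of 1,
awareness-marginal differences within 0.12, |rho| <= 0.12, median |slope|
<= 0.15) - i.e. the extra freedom went unused.

## Pipeline

The workbench runs simulate/ingest -> filter -> effects -> BF tests ->
regression -> GRT/SvA -> cross-block comparison, mirroring the block
structure: single-task (dissociation + regression, with awareness taken
from the visibility block), multiple-task (PAS-1-filtered and unfiltered
dissociation + regression + GRT), visibility (SDT + GRT), and the 2x2
block-by-measure comparison with correlations.  Stage failures are
recorded in the report and dependents skipped; the report validates
against the pydantic-generated JSON schema in `docs/report.schema.json`.
All randomness flows from the single config seed; reports are reproducible
byte for byte.

## Known limitations

- The GRT parameterization restricts individual differences to attention
  scaling and decision bounds; per-participant covariance shaping is out of
  scope, and real data violating this will push misfit into kappa and the
  bounds.
- The printed "percent accounted" of published fits is not comparable
  across packages because the statistic is not standardized.
- Bayes factors are prior-sensitive by design; all prior scales are
  surfaced in the API and config rather than hidden.
- The measurement-error regression assumes Gaussian effect noise with known
  per-participant SEs; heavy-tailed RT summaries would call for a robust
  observation model.
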