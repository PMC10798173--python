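# Methods

`tempopred` simulates and analyzes a behavioral auditory oddball experiment in
which the interval between successive tones (the stimulus-onset asynchrony,
SOA) is drawn from quantized Gaussian distributions of fixed mean (500 ms) and
varying standard deviation (0, 25, 50, 75, 100, 150 ms).  The package covers
the full chain: stimulus-timeline generation, a parametric synthetic listener,
trial-history statistics with 2-D binned performance maps, a sign-flip
cluster-based permutation test, and a generalized-linear-mixed-model (GLMM)
inference suite.  This note records the models, the parameter choices, and the
design decisions taken where the procedure was genuinely open.

## Stimulus model

Each block holds 410 trials, 56 of which are cued targets (deviant with
probability 0.5).  SOAs for targets and standards alike are drawn i.i.d. from
a discrete distribution on the 33-point grid 100, 125, …, 900 ms: the Gaussian
density with mean 500 ms and the condition's nominal STD is evaluated at each
grid point and renormalized.  Evaluating (rather than integrating) the density
per grid cell is the simplest construction that is exactly symmetric, so the
analytic mean is exactly 500 ms.  Truncation to the grid shrinks the realized
STD slightly below nominal (146.2 ms at nominal 150 ms; negligible below
100 ms); all analyses use the nominal STD as the condition label.

Target placement must satisfy three hard constraints: no target within the
first 10 trials, and 4–10 standards between consecutive targets.  These
constraints are *jointly* tight: 56 targets with mean gap 7 would need
10 + 56 + 55·7 = 451 trials, more than the 410 available, so gaps cannot be
i.i.d. uniform on [4, 10].  We therefore sample uniformly over the set of
feasible compositions — prefix in [10, 16], 55 gaps in [4, 10], tail in
[0, 10], standards summing to 354 — using exact dynamic-programming
composition counts and sequential conditional draws.  Every feasible
arrangement is equiprobable; the resulting marginal gap distribution is
necessarily skewed toward short gaps (mean ≈ 6.3).  The upper prefix bound
(minimum + one gap-range width) and the tail bound (one maximum gap) are
package conventions, since only the lower prefix bound is dictated by the
design.

Sessions hold 12 blocks, two per condition, ordered by rejection sampling of
multiset shuffles until no condition repeats consecutively — exactly uniform
over admissible orders.  A single seeded `numpy` generator is threaded through
session → block → trial, so a seed reproduces a session bit-for-bit.

## Synthetic listener

The observer is the data-generating stand-in for a participant.  Its accuracy
model is *linear in probability*:

    p = p0 + a_j − β_g·STD_global − β_l·STD_local + tuning(mean_local)
    p ← (1 − λ)·p + λ/2,     clamped to [0.05, 0.95]

with baseline `p0 = 0.80`, global slope `β_g = 0.006/25` per ms (0.6
percentage points lost per 25 ms of global STD), lapse `λ = 0.02`, subject
intercepts `a_j ~ N(0, 0.03²)`, and an optional zero-mean Gaussian tuning of
accuracy around a 500 ms local mean (amplitude 0 by default; its baseline is
removed over the 400–600 ms analysis range so switching it on does not shift
overall accuracy).  Linear-probability generation makes the planted
"percentage points per 25 ms" slope identical to the average marginal effect
the logistic analysis model is supposed to recover, which is what the recovery
checks exercise.  Local statistics enter through the sample mean/STD of the 4
SOAs preceding the target (window size configurable); the local slopes default
to zero so that the global-effect recovery is unconfounded.

Response times are gamma with shape 20 (CV ≈ 22 %, typical for RT data) and
mean

    E[RT] = 500 + b_j + (5/25 + s_j)·STD_global  (ms),

i.e. +5 ms per 25 ms of global STD, subject intercepts `b_j ~ N(0, 30²)` and
subject slopes `s_j ~ N(0, (1.5/25)²)`; the random slope mirrors the RT
model's random-effect structure on the analysis side, where the best model
carries both a random intercept and a random slope.  RTs are generated for
every target regardless of correctness.

Per-block rhythmicity ratings are linear in the condition STD (intercept 9,
slope −1 per 25 ms, Gaussian noise SD 1) clamped to the 0–10 scale, so the
periodic condition rates near ceiling and the 150 ms condition near 3 —
a steep, reliably detectable decline.

The 0.6 pp and 5 ms planted slopes are the study's reported effect sizes; the
baselines (p0, rt0), noise scales and random-effect SDs are package
configuration chosen at realistic magnitudes, not empirical claims.

### Staircase

SNR calibration uses a 75-tone periodic stream with a target every 2–3 tones
(≈ 25–37 discrimination trials) and a transformed 3-down-1-up rule, whose
asymptote (79.4 % correct) matches the ~80 % calibration target.  The
psychometric function is a cumulative Gaussian from the 0.5 chance floor
(binary standard/deviant choice).  Because so few trials are available, the
staircase starts 1-down-1-up until the first error (the transition is not
counted as a reversal), and the 4 dB step halves after each of the first two
reversals but never below 2 dB — with ~30 trials a smaller step cannot recover
from the initial descent and biases the track low.  The returned SNR is the
mean of the last four reversals; fewer than four reversals raises a
convergence warning and returns the last SNR.

## Trial-history statistics

For a target at trial *i*, the "N previous SOAs" are the SOAs of trials
*i*, *i−1*, …, *i−N+1* — the window *includes* the interval immediately
preceding the target, so N = 1 reproduces the last-SOA analysis.  Local means
use N in 1..7 and local STDs (sample, n−1 denominator; a population-STD switch
exists) N in 2..7.  Targets never occur before trial 11, so windows never
reach the undefined first-trial SOA.

Per participant, targets are binned into overlapping 2-D windows: mean
centers 400–600 ms every 10 ms with half-width 20 ms, STD centers 10–100 ms
every 5 ms with half-width 10 ms.  Center spacing is a package choice (the
window half-widths are given, the grid step is not); 10/5 ms steps give ≥ 50 %
overlap between adjacent windows, consistent with the premise that adjacent
samples are correlated.  Window boundaries are inclusive, so ties enter both
adjacent bins.  Bins with fewer than 5 trials are invalid.  Valid-bin values
are z-scored per participant (mean 0, sample SD 1); maps with fewer than two
valid bins or zero variance become all-invalid with a warning.  The group
array keeps only bins valid for *every* participant (intersection), because
the permutation test needs a complete participants × bins matrix; per-analysis
pooling over matched N (a target contributes one row per N in 2..7) is the
pipeline default and any single (N_mean, N_std) pair can be requested instead.

## Cluster-based permutation test

One-sample t against zero per jointly valid bin; two-sided p ≤ 0.05 defines
cluster candidates; candidates of equal sign merge under 4-neighbour (rook)
adjacency on the bin lattice — diagonal adjacency is deliberately excluded;
the cluster statistic is the sum of member t-values.  The reference
distribution comes from 1000 sign-flip permutations (each participant's whole
map multiplied by ±1), the identity flip included; per permutation the signed
statistic of the most extreme cluster is recorded, and an observed cluster is
significant if its statistic falls below the 2.5th or above the 97.5th
percentile of that signed distribution.  Cluster p-values are the +1-corrected
two-sided exceedance ranks, so p ≥ 1/(n_perm+1).  A classical max-|stat| null
with a 95th-percentile cut is available as a config switch; both control
two-sided family-wise error at 5 %.  Zero-variance bins (possible only in
degenerate fixtures) are treated as supra-threshold with the sign of their
mean so that degenerate inputs behave deterministically.

## Mixed models

Accuracy is binomial-logit, RT is gamma (log link by default, identity link
for the RT-slope recovery so the fixed slope reads directly in ms per ms),
ratings are gaussian.  Subject random intercepts (plus an optional random
slope on global STD with free correlation, log-Cholesky parameterized) are
integrated out per subject by a Laplace approximation; conditional modes are
found by damped Fisher scoring (expected-information weights; for the
canonical binomial-logit these equal the observed curvature), and the outer
optimization over fixed effects, covariance parameters and the family
dispersion uses BFGS with a bounded Nelder-Mead polish when BFGS halts on
finite-difference precision loss.  Standard errors come from the numerical
Hessian of the marginal deviance.  Fits are deterministic given the data; a
random-intercept SD below 1e−3 raises a boundary flag rather than an error.
Against `lme4::glmer` (Laplace) on a shared dataset the fixed effects,
random-intercept SD and log-likelihood agree to ~1e−3 (see the test suite).

Inference mirrors the study's workflow: likelihood-ratio tests for stepwise
model comparison (boundary-null caveats for random-slope additions are noted,
not "corrected"); Type II Wald chi-square per fixed term; Tukey-adjusted
pairwise contrasts of estimated-marginal means over the 6-level condition
factor, using the studentized-range distribution with large-sample residual
df (the mixed-model df question is deliberately sidestepped; the unadjusted p
uses the same t reference so the k = 2 identity holds exactly).  The reported
"% per 25 ms" is the average marginal effect of a +25 ms increment on
response-scale probability, averaged over the observed data at the
conditional modes — the estimand that equals the linear-probability planted
slope.  The local-vs-global models regress accuracy (and RT) on global STD,
local STD(N) and last SOA, all scaled per 25 ms, and report odds ratios with
Wald 95 % CIs; an OR below 1 means a +25 ms increase of the predictor lowers
the odds of a correct response.  The 500 ms restriction keeps targets whose
preceding SOA is exactly 500 (exact on the 25 ms grid).  Rater exclusion uses
the per-subject OLS slope of rating on condition STD as the regression score
and a ±1.5 IQR Tukey fence with linear-interpolation quartiles.

## Problem sizes and calibration experiments

The recovery experiments simulate 20 replicate cohorts of 19 subjects × 12
blocks (≈ 12 768 target responses per cohort) and require the averaged
recovered accuracy decline within ±0.15 pp/25 ms of the planted 0.6 and the
averaged RT slope within ±1.5 ms/25 ms of the planted 5.  Staircase
calibration averages 100 replicate runs (target 80 ± 5 % correct).  Error
control uses 500 pure-noise datasets (19 × 10 × 8 maps, 1000 permutations
each) for cluster family-wise error ≤ 0.075, and 500 null replicates for the
Wald test (10 subjects × 50 trials each) with rejection rate in 0.05 ± 0.025.
Other stochastic unit tests assert 3-sigma Monte-Carlo bands around their
nominal levels at sizes fixed in the test code.

## What the generator does and does not emulate

The synthetic cohort reproduces the design numbers, the planted global
slopes, subject heterogeneity, gamma RT noise, rating decline and the
statistical families assumed by the analyses.  It does not emulate: learning
or fatigue across blocks, hazard-rate or foreperiod effects beyond the
optional local-mean tuning, lapses correlated with time, non-gamma RT tails,
response omission, or acoustic reality behind the SNR axis (the staircase's
dB scale is abstract).  Passing recovery tests therefore demonstrates that
the estimators recover what the generator planted under the assumed families
— not that real listeners obey those families.

## Known limitations

* The gamma-identity model requires a positive mean; data far from the RT
  scale of the defaults may hit the positivity guard during optimization.
* Laplace (rather than adaptive quadrature) can bias variance components
  for small clusters with binary data; with ≥ 112 targets per subject the
  bias is negligible at the tolerances used here.
* Tukey adjustment with large-sample df is mildly anticonservative for very
  small cohorts; the pipeline warns when fewer than 5 subjects are fit.
* The permutation reference records one extreme statistic per permutation;
  with several strong clusters of mixed sign this is slightly conservative
  compared to per-sign nulls.
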