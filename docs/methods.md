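# Methods

This note documents the models, estimators, simulator and numerical
choices implemented in `stopkin`.

## Task and data model

A session is a sequence of go and stop trials of a mouse-tracking stop
signal task.  The cursor is recorded as (t, x, y) samples at the monitor
refresh rate; x is measured from the home-pad centre, y from the home-pad
top, y increasing toward the targets.  Rectangles (home pad, two targets)
are half-open in pixel coordinates: the reaction time (RT) is the first
sample time strictly outside the home pad (minus the go-signal onset), the
total response time (TRT) the first sample inside a target box within the
1.4 s response deadline.  No interpolation is applied before the first
recorded exit — with data recorded from movement onset, the first exit
sample is the operational response.

Two definitions of stop success drive two independent SSD staircases:
*home* (cursor never leaves the pad) and *target* (cursor never enters a
target).  Both flags are computed for every stop trial regardless of the
staircase that adjusted on it.

Go errors take exactly one label per trial: `omission` (never left the
pad), `choice_error` (entered the non-cued target first), `missed_target`
(left the pad, never entered a target), else `none`.

**Participant exclusion** retains a session only if, per staircase, the
mean failed-stop latency is below the mean go latency (home compares RTs,
target compares TRTs — each staircase's own response definition), stopping
succeeds on 25–75% of its stop trials, and the go error rate is below 20%.

**Latency outlier rule** (single pass): values below 100 ms, or outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], are removed.  Quartiles use linear
interpolation between order statistics and are computed once on the full
input; the filter is not re-applied after removal.  A second pass can
therefore remove additional values — the single-pass convention is the
documented behaviour.

## Kinematic single-trial estimators

For each trial the *resultant displacement* is the Euclidean distance from
the home-pad exit sample; the *resultant velocity* is its derivative by
central differences on the (possibly non-uniform) sample grid, one-sided at
the endpoints (`np.gradient`).  Velocity is the derivative of the
displacement scalar, not the norm of component velocities — the two differ
on curved paths, and the scalar form is what the landmark definitions need.
No smoothing is applied before differentiation (a smoothing hook exists but
defaults off).  Argmax ties resolve to the earliest sample, because
stopping is about the first halt.

* `SSRT_K` (home staircase): on failed stops that still halted short of the
  target, peak-velocity time − stop signal time.  The peak marks the moment
  the interrupted movement begins to decelerate.
* `SSRT_K` (target staircase): on successful stops with movement initiated,
  maximum-displacement (halt) time − stop signal time.  At the long SSDs the
  target staircase tracks, the stop signal arrives when velocity is already
  declining, so the halt is the usable landmark.
* `TF_K`: fraction of home-staircase stop trials on which the cursor
  entered the cued target within the deadline.  At home-staircase SSDs the
  stop process has several hundred ms to act, so an un-stopped movement is
  attributed to a trigger failure (the stop process never launched).

Negative single-trial SSRTs are legal outputs (landmark before the stop
signal); they are removed by the standard <100 ms / IQR filters before
summary, which is also why those filters exist.  Trigger-failure trials are
excluded from the home SSRT_K distribution — they contain no stop process
to time.  `SD-SSRT_K` is the sample standard deviation (ddof = 1) of the
filtered single-trial values; it is flagged undefined below 2 usable
trials.

Race-consistency regressions (per staircase, single-trial OLS /
logistic): failed-stop latency ~ SSD (positive under the race), movement
amplitude ~ SSD over initiated-but-stopped trials (positive), SSRT_K ~ SSD
(negative: at long delays only fast stop processes win), and the logistic
inhibition function (stop success ~ SSD).  Regressions with fewer than 10
qualifying trials, degenerate SSD variance, or separable logistic fits are
flagged rather than reported.

## Race-Model integration estimator

`SSRT_RM = Q_go(p_respond) − mean SSD`, with `p_respond = 1 − pStop` pooled
over the staircase's stop trials (pooling matches the staircase design; no
per-SSD weighting).  The quantile uses the deterministic 1-based rank rule
`ceil(p_respond · N)` on the ascending-sorted go latencies; interpolating
variants move the estimate by less than one quantile step and were rejected
for determinism.  Go trials without the relevant latency (omissions; for
the target staircase also missed targets) are assigned the maximum observed
latency before ranking — omission rates in this task are a few per mille,
so the choice is immaterial.  `p_respond` of exactly 0 or 1 is refused with
an explanatory error.

## Two-runner ex-Gaussian race model with trigger failures

Finishing times are ex-Gaussian: normal(μ, σ) plus exponential(τ); mean
μ + τ, variance σ² + τ².  Densities and CDFs use the scaled complementary
error function: with z = (t − μ)/σ and a = (σ/τ − z)/√2,

    f(t) = erfcx(a) · exp(−z²/2) / (2τ),     F(t) = Φ(z) − τ·f(t),

switching to the normal-CDF form f = exp(a² − z²/2)·Φ(−√2·a)/τ where a < 0
(the exponential tail), so the forms are overflow-free for all parameter
regimes including τ → 0.

On a stop trial at delay `ssd`, the stop runner is omitted with probability
TF = Φ(θ_TF) (probit scale).  The signal-respond density and the
inhibition probability are

    f_SR(t) = f_go(t) · [TF + (1 − TF)·(1 − F_stop(t − ssd))]
    p_inhibit(ssd) = (1 − TF) · ∫ f_go(t) · F_stop(t − ssd) dt

with F_stop vanishing at negative arguments; their sum over outcomes is 1
exactly.  The public `p_inhibit` uses adaptive quadrature (tolerance 1e−8)
over the region where both factors have mass plus an analytic tail
correction (beyond the upper limit F_stop is 1 to working precision, so the
remainder is go survival mass).  The likelihood uses a fixed composite
Gauss–Legendre rule (order 12) with panel edges at landmarks of the go
density (μ ± kσ, exponential-tail multiples of τ), vectorised over SSDs;
it agrees with the adaptive rule to ~1e−4 in the worst degenerate corners
and ~1e−9 in realistic regimes.

The subject-level log likelihood is the sum of go-trial log f_go,
signal-respond log f_SR, and per-SSD successful-stop counts times
log p_inhibit.  Trials removed by the outlier filters never reach the
likelihood; go trials with errors are excluded (choice errors are rare
enough in this task to justify the two-runner rather than three-runner
race).

**Priors and sampling.**  Per-subject fits use uniform priors truncated at
0–2000 ms (μ), 0–1000 ms (σ, τ) and −6..6 (θ_TF).  Sampling is seeded
component-wise Gaussian random-walk Metropolis, 3 independent chains, 50%
burn-in, per-coordinate proposal scales adapted during burn-in only
(Robbins–Monro toward 0.44 acceptance) and frozen afterwards so the kept
draws satisfy detailed balance.  Chains run in blocks until the split-chain
Gelman–Rubin R̂ is below 1.1 for every parameter or an iteration cap is
reached; the result records which occurred (non-convergence is a flagged
result, not an exception).  Internally the time parameters are sampled in
seconds; everything is reported in ms.  A start-value heuristic uses go-RT
moments and an integration-method SSRT.

**Hierarchical fit.**  Abbreviated per-subject fits set the start values
and centre the normal hyper-priors of the group-level means (hyper-prior
scale 1 on the sampling scale).  Subject parameters are drawn from
N(group mean, group SD), truncated as above except that θ_TF is
untruncated.  The group-level SDs are *estimated* under a half-normal prior
of configurable scale (default 1 on the sampling scale).  The convention
"group-level SDs set to 1" is ambiguous between a fixed value and a prior
scale: fixing them at 1 second leaves the group means prior-dominated and
essentially unidentified, so estimation is the default and
`estimate_group_sd=False` preserves the fixed-value reading.  The sampler
is Metropolis-within-Gibbs: exact (truncated-)normal Gibbs updates for the
group means, log-scale Metropolis for the group SDs (their conditionals
need no likelihood evaluations), and component-wise random-walk Metropolis
for each subject's vector.  R̂ is computed on the group-level means.

With very low trigger-failure prevalence, hierarchical shrinkage pulls the
group TF posterior hard toward zero even when a little TF was generated —
the same behaviour reported for hierarchical fits of tasks with ~1% TF.
This is a property of the pooling, not a defect; the per-trial kinematic
TF_K count does not shrink.

**Posterior predictive checks** draw parameter vectors from the joint
posterior, simulate replicate datasets of the same size at the observed
SSDs, and compare observed go-RT quantiles, failed-stop-RT quantiles, the
inhibition function over SSD quartile bins, and the failed-stop-RT ~ SSD
slope against the central 95% predictive bands; statistics outside the band
are flagged.

## Ground-truth simulator

The simulator draws the race at RT level and renders consistent
trajectories, logging every latent variable so each estimator can be scored
against its own landmark.

* Go finishing times (pad exit) are ex-Gaussian; defaults μ=355, σ=50,
  τ=70 ms (mean 425 ms, within-subject SD 86 ms).  Stop finishing times
  default to μ=270, σ=35, τ=50 ms (SSRT 320 ms, SD-SSRT 61 ms); trigger
  failures default to 1%.  These defaults reproduce the magnitudes
  reported for online mouse-tracking stop tasks (go RT ~425 ms, TRT
  ~835 ms, home SSD ~100 ms, target SSD ~500 ms, pStop ~50%, TF ~1%); the
  within-subject RT spread is set to a typical reaching-RT value, as only
  across-subject spreads are commonly reported.
* Structure: 18 blocks × 32 trials, 25% stop trials, four per staircase per
  block, sides balanced, order shuffled.  SSD staircases step by 33.3 ms
  rounded to the nearest frame, floored at 33.3 ms, up after success and
  down after failure.  SSDs are frame-quantised ("actual" vs intended).
  Go-error injection defaults: 0.2% omissions, 0.2% choice errors, 4%
  missed targets.
* Geometry is scaled to a typical browser window (1627×834 px):
  8 px home pad, 40 px targets at 431 px eccentricity along ±45°.
* Trajectories are minimum-jerk: displacement D·(10s³ − 15s⁴ + 6s⁵) with
  s = t/T.  The full min-jerk duration defaults to T = 600 ms, which puts
  pad exit at ~70 ms and target entry at ~470 ms after movement onset —
  i.e. a pad-to-target movement time of ~400 ms, matching the reported
  TRT − RT magnitude for this task.  Movement onset is placed so that the pad-exit time equals the
  drawn go RT.
* Race outcomes are canonical: the home staircase stops successfully iff
  stop completion (SSD + stop RT) precedes pad exit — the movement is then
  never launched; the target staircase iff it precedes natural target
  entry.  Interrupted movements follow the min-jerk profile until stop
  completion, then the velocity decays as a raised cosine over the braking
  duration (default 100 ms), so the velocity peaks at stop completion and
  the halt (maximum displacement) follows one braking duration later.  If
  braking would carry the cursor into the target despite the race saying
  "stopped", the braking duration is shortened so the halt lands 2 px short
  of entry — this keeps the rendered outcome identical to the race outcome,
  which the staircases and all estimators rely on.
* Consequently the two kinematic landmarks bracket the stop completion:
  the velocity peak sits at it, the halt one (possibly shortened) braking
  duration after it.  The empirical offset between the two landmarks in
  real data is unknowable from summary statistics, so the braking duration
  is a configuration knob, both ground truths are logged per trial
  (`peak_velocity_time`, `halt_time`), and each estimator is validated
  against its own landmark.
* Delay period (go onset 1–1.5 s after trial start) is bookkeeping only.
  Trajectories are straight lines to the aim point; optional perpendicular
  noise defaults off (no estimator needs curvature).  Sessions are
  byte-identical under identical seed and configuration.

What the simulator does *not* emulate: biomechanical variability (inertia,
wrist vs arm), pointer-acceleration artefacts, curved or two-step
movements, strategic slowing, and any dependence of the TF rate on SSD
(TF is constant across delays, the same assumption the models make).
Passing recovery tests therefore show that the estimators are correct for
movements whose interruption behaves like a braked minimum-jerk reach —
not that braking in human data is 100 ms, nor that real halts follow stop
completion by a fixed offset.

## Precision analysis

For one subject's per-trial metric values, x trials are resampled *without
replacement* (the subject's own finite trial set) for x in {5, 10, …, 70},
1000 times per grid point; the "true" value is the full-sample summary.
Two decision rules are implemented for "estimates within ±5% of the true
value":

* `reps` (default): smallest x at which ≥90% of resampled estimates fall
  within the band — for an unbiased statistic this reflects sampling
  precision, which is what trial-count planning needs;
* `mean`: smallest x at which the *mean* of resampled estimates is within
  the band — trivially satisfied for unbiased statistics, informative for
  biased ones (e.g. the SD).

With fewer values than the grid maximum the grid is truncated and flagged.
Required counts are non-increasing in tolerance and non-decreasing in the
metric's dispersion (both property-tested).

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run at desk scale: cohorts of
3–12 simulated subjects (18-block sessions; 40-block sessions where ≥72
usable stop trials per staircase are needed), 20 replicate subject-level
fits at 600 go / 200 stop trials with 3 chains × 1400 iterations (50%
burn-in, continued up to 5600 on non-convergence), hierarchical fits of
5–6 subjects at 800 sweeps, and Monte-Carlo oracles of 10⁵–10⁶ draws.

## Known limitations

* Home-staircase SSRT_K is measured on failed stops (biased toward slow
  stop processes); target-staircase SSRT_K on successful stops (biased
  fast) and offset by the braking duration.  The simulator exposes both
  biases rather than hiding them; on real data the model-based estimates
  are the calibration reference.
* The IQR outlier filter truncates the right tail of skewed SSRT
  distributions, shrinking SD-SSRT_K by roughly 5–15% under ex-Gaussian
  stop processes.
* The hierarchical TF estimate collapses toward zero in low-TF regimes
  (see above); per-trial TF_K is the sensitive measure there.
* `p_respond` pooled across SSDs is the staircase-appropriate choice but
  differs from fixed-SSD designs; no per-SSD integration weighting is
  provided.
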