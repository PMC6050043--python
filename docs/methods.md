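# Methods

This note documents the models, estimators and numerical conventions in
`ramptime`, the parameters that matter, and what the synthetic-data tests
do and do not establish about real recordings.

## Task and data model

A session is one neuron's set of self-timed saccade trials.  Each trial
has a mandatory-interval condition (short 400–700, medium 1000–1600, long
2400–3100 ms), a saccade direction (contra/ipsi), fixation-point and cue
onset times on a per-trial clock, the saccade time, and a landing error.
Spikes are per-trial sorted timestamps in ms.  Trials whose saccade lands
more than 5° from the cue are excluded; early saccades (before the
mandatory minimum) are retained, since the subject was still timing the
interval.  All times are handled in integer milliseconds with half-open
windows [start, end); session files round spike times to the 1-ms grid
(canonical form).

## Synthetic sessions

The generator exists so every stage of the pipeline can be exercised with
known ground truth.  It emulates:

* **Latencies** — lognormal per condition, moment-matched to (mean, sd).
  Defaults put the mean at the mandatory-window center and the sd at a
  quarter of the window width (550 ± 75, 1300 ± 150, 2750 ± 175 ms), the
  behavior of a subject rewarded for saccades inside the window.  With
  probability `early_fraction` (default 0.1; observed rates in this kind
  of experiment span roughly 6–35%) the latency is drawn from the same
  lognormal upper-truncated at the mandatory minimum, so mis-timed
  saccades cluster just below the boundary.
* **Firing** — a piecewise-linear intended rate per trial: baseline, a
  linear ramp from onset, clipping at the peak rate, a hold through
  saccade + 150 ms, and a 300-ms linear decay back to baseline
  (movement-related activity decays over hundreds of ms; an instantaneous
  drop would put an artifactual cliff into cue-aligned averages).
  Spikes are drawn by thinning against the rate maximum, which is exact
  for bounded rates.  A per-trial lognormal excitability gain
  (`trial_gain_sd`) makes the process doubly stochastic.
* **Regimes** — `tracker` neurons start ramping at a fixed post-cue onset
  (default 100 ms) with slope set so the rate peaks at the condition's
  mean latency; within-condition trial variability is injected only as
  gain noise over the final 200 ms (late coupling).  `trigger` neurons
  start ramping a fixed lead time before their own saccade (default
  500 ms) at fixed slope, with the lead jittered 8% per trial, so trial
  variability enters at ramp onset.  Early-saccade trials use the same
  condition ramp as every other trial; giving them steeper own-latency
  ramps would concentrate trigger-like trials in the fast latency tercile
  and destroy the tracker regime's late-variation signature.
* **Populations** — across neurons, baseline and peak rates get 15%
  lognormal jitter and ramp onsets (or lead times) Gaussian jitter of
  75 ms, so the population-mean onset is the recovery target.
  Structure-typical templates: caudate-like trackers fire ~2 Hz at
  baseline and ~50 Hz at peak with gain sd 0.5, which reproduces the high
  across-trial baseline CV of striatal neurons (~1.3–1.5, mostly the
  Poisson floor of a near-empty 300-ms count window); dentate-like
  triggers fire ~30 Hz baseline, ~80 Hz peak, gain sd 0.385 (CV ~0.5).
* **Eye traces** — 1-kHz position with fixation noise and a smoothstep
  displacement whose duration follows the saccadic main sequence
  (2·amplitude + 20 ms), giving peak velocities well above the 40°/s
  detection threshold for amplitudes ≥ 3°.
* **Inactivation** — muscimol shifts the latency mean by
  `inactivation_shift_ms` and scales its sd by `inactivation_sd_scale`;
  saline applies no change.

What the generator does **not** emulate: bursting and refractoriness
(spiking is Poisson conditional on the rate), visual transients after cue
onset, direction tuning dynamics, slow drifts across a session, or
correlated noise between neurons.  Passing tests therefore demonstrate
the estimators' correctness and calibration under the assumed statistical
structure, not robustness to every property of real recordings.

## Spike density and normalization

Per-trial spike trains aligned on the cue or the saccade are binned at
1 ms, smoothed with a Gaussian kernel (σ = 15 ms) truncated and
renormalized at the window edges (the smoothed window indicator divides
the trace), and averaged across trials.  One spike therefore integrates
to one spike away from the edges and no rate mass is invented at the
boundary.

Per-neuron normalization subtracts the pre-cue baseline (mean rate over
[−300, 0) ms before the cue, conditions pooled) and divides by the
neuron's peak modulation.  The modulation depth is estimated as the
largest, across conditions, of the mean baseline-subtracted rate in the
perisaccadic window [0, 150) ms of the saccade-aligned trace — ramping
activity in this preparation peaks at movement onset, and a window mean
is far less biased than the maximum over every 1-ms bin, which at
realistic trial counts overshoots the true depth by 25–30% and deflates
every normalized slope.  Because a maximum over three noisy condition
means is still biased upward, the pipeline subtracts the expected maximum
of three centered Gaussians with the empirical standard errors
(0.8463 × mean SE).  Residual slope bias after this correction is a few
percent.

## Delayed-ramp regression

The population trace is fit with f(t) = b for t < t₀ and b + k(t − t₀)
for t ≥ t₀ by least squares over the window from 300 ms before the cue
(400 is a supported alternative; both window starts appear in the
literature this procedure follows) to the mean saccade latency, excluding
[cue + 50, cue + 250) ms to remove the visual transient.  t₀ is profiled
over every grid point: conditional on t₀ the problem is linear and the
normal equations are solved from suffix cumulative sums, so the whole
profile costs O(T) and the minimizer is exact; the earliest t₀ wins ties,
and a constant trace returns k = 0 with t₀ at the window end by
convention.  Saccade-aligned fits use the same span mapped through the
mean latency (window ending at t = 0, exclusion window shifted by the
mean latency — it is applied in all conditions, including the short one
where it overlaps the ramp, since it only removes samples).

Confidence intervals resample neurons with replacement (B = 1000 by
default), re-normalize, re-average and re-fit; per-resample RNG streams
derive from (seed, resample index), so results are order-independent.
Cross-structure significance uses the paired difference distribution over
resample index (central 95% interval excluding zero), the stricter
standard reading of "bootstrap CIs".

**Known bias.**  Trials whose saccade precedes the fit-window end — early
saccades, plus the lower tail of the latency distribution — stop ramping
and decay inside the window, flattening the population trace near its
end.  On synthetic tracker populations this biases the fitted onset early
by ~20–40 ms in the medium and long conditions (the short window is
barely affected).  The bias is a property of the fitting procedure
applied to behavior with latency dispersion, is identical in every
neuron-resample, and is therefore invisible to the bootstrap: the
percentile intervals undercover the true onset (≈ 75–85% instead of 95%
at 50 homogeneous-onset neurons).  Onset *differences* between
structures, and slope ratios between conditions, are much less affected
because the bias is shared.

## Latency-tercile divergence

Trials of one condition (preferred direction by default) are ranked by
latency and cut into three contiguous groups, remainders to the earlier
groups, ties broken by trial id.  At every millisecond a one-way
repeated-measures ANOVA with neurons as subjects and tercile as the
within-subject factor is computed from explicit sums of squares,
F(2, 2(n−1)); no sphericity correction is applied (with three levels and
the persistence rule below the uncorrected per-ms screen is the intended,
slightly liberal choice; a Greenhouse–Geisser switch is config-exposed).
The divergence onset is the earliest time with p < 0.01 at every
millisecond of a 40-ms run.  The analysis window runs from cue onset to
the mean latency (cue frame) or the mirrored span ending at the saccade.

Under exchangeable null groups the per-ms type-I rate is calibrated
(≈ 0.01) and the persistence rule fires spuriously at ≈ 8.6 × 10⁻⁶ per
millisecond, i.e. in ~2–3% of 2.7-s windows — isolated flickers are
crushed, but a kernel-smoothness-scale run can survive.  The onset
estimate ignores trial-by-trial baseline fluctuation, which is reproduced
in the result metadata as a caveat rather than modeled.

**Bootstrap.**  Resampling neurons with replacement is invalid for this
nonlinear detector if duplicates are exact copies: a duplicated subject
injects the same noise pattern coherently into the F numerator and
produces spurious early onsets (observed: resample medians >1.5 s earlier
than the point estimate).  The pipeline therefore uses a hierarchical
bootstrap: neurons are resampled with replacement, and a neuron drawn m
times has its trials partitioned into m disjoint chunks, one per copy, so
copies are conditionally independent given the neuron.  Each neuron's
normalization scale is estimated once from all its trials (re-estimating
it from 2–3-trial chunks is unstable enough to distort the F).  After
this fix resample medians match point estimates and the spurious-early
fraction drops to ≈ 1%.  The lower-level `bootstrap_divergence` function
retains plain neuron resampling for API symmetry with the ramp bootstrap
(its degenerate examples — identical neurons give zero-width intervals —
hold there exactly).

## Epoch statistics, selectivity, inactivation

Epoch rates are counts over fixed windows (baseline 300 ms before FP
onset; visual 200 ms after cue; delay 350 ms starting 500 ms before the
saccade; saccade 150 ms before the saccade) divided by window length.
Task-relatedness requires one-way ANOVA across the four epochs and the
Scheffé delay-vs-baseline contrast both at p < 0.05; the Scheffé
statistic is computed from its F-based definition
L²/((k−1)·MSE·Σc²/n) against F(k−1, N−k), not a package post-hoc helper.

Duration selectivity normalizes the three presaccadic (200 ms) condition
rates to sum to one and embeds them at x = n_m − n_l, y = n_s·√3; the
triangle has vertices (0, √3), (1, 0), (−1, 0) and the distance is taken
from the centroid (0, √3/3), the unique symmetric reading of "center".
Selective neurons have one-way ANOVA p < 0.01 across conditions, with the
preferred condition the argmax mean.  Structures are compared with the
asymptotic two-sample Kolmogorov–Smirnov test on centroid distances.

Inactivation sessions compare pre/post latency samples per
(condition × direction × task) cell: median shift with a two-sided
rank-sum test (exact null up to 60 trials per sample, asymptotic beyond),
dispersion with a two-sided variance-ratio F, both Bonferroni-corrected
within the session across tested cells (the minimal consistent family;
config-exposed).  Population effects are paired t-tests across sessions
on median/SD/CV changes with 95% CIs; a zero-variance nonzero-mean
difference vector is reported as significant-by-degeneracy rather than an
infinite statistic.  Saline sessions run the identical statistics.  Note
that Bonferroni makes the per-session familywise error ≈ 5% by
construction, so the expected fraction of clean zero-effect sessions sits
just above 95% (exactly computable from the discrete rank-sum null:
95.1–96.3% depending on trial count).

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use populations of 50 neurons
(recovery experiments; 20 replications with B = 200) and 100/76 neurons
(regime contrasts, the published sample sizes), 20 trials per
condition × direction, 50 pre/post trials per inactivation cell, and
40–100 null seeds for detector calibration — sizes chosen so the full
suite completes in a few minutes while keeping Monte-Carlo error well
inside the asserted margins.  Numerical tolerances: oracle equivalence of
the ramp fit to 1e-9 on slopes and exact on onsets; kernel mass to 1e-6;
geometry exact to floating point; statistical assertions use binomial
99% bands around nominal rates.
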