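# Methods

This note documents the models, conventions and design choices behind the
toolkit, in the spirit of a statistical package's model documentation.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task structure and sequence sampling

A block is defined by `BlockConfig`: `n_trials` (32), `n_inhibitory` (8),
`lead_in` (3 forced prepotent trials), run caps `max_run_prepotent` (5) and
`max_run_inhibitory` (2), and `n_blocks` (1 for the toddler task, 3 for the
fast-paced adult task, i.e. 96 trials).  The lead-in is implemented as
*exactly* `lead_in` forced prepotent trials followed by constrained
randomisation — the randomiser may of course place further prepotent trials
directly after the lead-in, so "at least 3" holds by construction.  Run caps
are enforced *within* a block only; blocks are separated by breaks and each
restarts with its own lead-in, so runs do not carry across block boundaries.

The original task software does not document its randomiser's distribution
over valid sequences; this implementation commits to the **uniform**
distribution over all constraint-satisfying arrangements.  Uniformity is
implemented exactly rather than by rejection: a dynamic program counts the
valid completions of every partial state (trials remaining, inhibitory
trials remaining, last condition, current run length), and each trial is
drawn with probability proportional to the completion counts.  This has
three advantages over rejection sampling: it is uniform by construction (no
positional bias to audit), it terminates in `O(n_trials)` draws, and an
unsatisfiable configuration manifests as a zero count and raises
`UnsatisfiableConfigError` instead of looping.  The run caps are strict:
a degenerate all-prepotent block (`n_inhibitory = 0`) is only satisfiable
when `max_run_prepotent >= n_trials`.

Counterbalancing alternates the prepotent location (top/bottom) across the
participant list in order, so the two locations differ in count by at most
one, and is fixed across a participant's longitudinal visits.

## Cleaning and scoring conventions

* Trials with first-touch RT below the variant floor (300 ms toddler,
  200 ms adult) are recoded `invalid_fast` and enter neither the accuracy
  nor the RT set; externally coded invalid trials (finger at onset,
  intervention, accidental touch) are likewise dropped from both.
* The first trial of a toddler session is discarded *after* sequence
  validation and before all counts, because the experimenter points to the
  correct location on it.  The adult variant has practice trials instead
  and keeps trial 1.  The >60% inclusion criterion is computed after the
  discard, on the cleaned accuracy set.
* The RT set additionally requires a correct response and RT < 5000 ms.
  Correct trials slower than the ceiling still count for accuracy
  (a distracted-but-correct response is a correct response).
* Inclusion is **strict**: prepotent accuracy of exactly 60% excludes.
* Percentages live on the 0–100 scale everywhere; adjusted AccD divides by
  the prepotent *proportion* (pct/100), so it equals AccD at 100% prepotent
  accuracy and grows as prepotency weakens.
* Medians use the even-count convention (mean of the two central values)
  shared by session scoring and the simple-RT summary.  RTD is left
  undefined — not zeroed — when a condition has no scorable correct RT;
  downstream analyses drop such sessions pairwise.
* The >3 SD screen for extreme difference scores is an explicit flagging
  helper (`flag_outliers`), never silent removal.  Note |z| cannot exceed
  (n−1)/√n, so the screen is only informative at moderate n.

## The generative participant model

Each trial is, in order of precedence: an externally-coded invalid trial
(probability `p_invalid`, code drawn uniformly from the three external
codes), an anticipation (`p_anticipation`: RT uniform on [80 ms, floor),
touched location random), a distraction (`p_distraction`: RT = ceiling +
Exp(1500 ms), accuracy drawn normally), or a regular response.  Regular
correctness is Bernoulli with the condition's probability; regular RT is
ex-Gaussian (Normal(μ, σ) + Exp(τ)), truncated by resampling to
[floor, ceiling) so that the injected event rates stay exact.  The
inhibitory cost is a location (μ) shift applied to *correct inhibitory
trials only* — error RTs are generated but never scored, matching the
correct-trials-only RT analyses.  In the unresponsive variant an incorrect
first touch is followed by a logged corrective touch; accuracy and RT are
always taken from the first touch.

Ex-Gaussian is the field's standard right-skewed RT law.  Published group
data for the toddler task include accuracy percentages but no RT
distributions, so toddler RT parameters (μ ≈ 0.9–1.0 s, σ ≈ 200 ms,
τ ≈ 350–450 ms, inhibitory cost 220–250 ms) are plausible choices for
unhurried toddler touch responses and should not be treated as fitted
values.  Adult-version profiles use the printed condition medians (≈581 ms
prepotent, ≈669 ms inhibitory) and group RTD values (≈102/57/95 ms for
children / young adults / older adults) to set locations and costs.

### Cohort heterogeneity and the longitudinal trait

Between-subject heterogeneity is Gaussian on the logit of inhibitory
accuracy with SD `between_subject_sd` (prepotent accuracy gets half that
SD; the RT location a 10% log-normal spread).  The logit *centre* is solved
numerically (Gauss–Hermite quadrature + Brent root-finding) so that the
**population mean** accuracy equals the profile's target group accuracy;
without this, Jensen's inequality would shrink group means toward 50% and
the profiles would miss the group accuracies they are calibrated to
(63% → 89% inhibitory from 18 to 24 months, 74% → 92% from 24 to
30 months, prepotent >90% throughout, near-ceiling adult performance).

In the longitudinal design each participant's visit-level trait is
`√r·z_shared + √(1−r)·z_visit`, giving any two visits latent correlation
`r = stability_r`.  Observed cross-visit score correlations are attenuated
by score reliability; the test suite checks this against a parallel-forms
oracle (two sessions simulated at the same visit, whose correlation *is*
the reliability).  For negative `stability_r` the trait sign alternates
across visits — exact only for two visits, which is the tested case.

What the simulator does **not** emulate: learning/fatigue within a session,
trial-order effects beyond the design constraints, RT autocorrelation,
choice errors on stop-signal go trials, and coder disagreement (validity
arrives as already-coded flags).  Passing tests therefore validate the
scoring and statistical machinery under the stated generative assumptions,
not the behaviour of real children.

## Stop-signal engine

The default structure is 5 blocks × 4 sub-blocks × 16 trials (12 go +
4 stop, directions balanced within trial type, order shuffled per
sub-block).  The staircase moves the SSD +50 ms after a successful stop and
−50 ms after a failed stop, only on stop trials.  The initial SSD (250 ms)
and the clamp bounds (0–1150 ms) are not documented for the reference
battery and are configurable conventions here.

Stopping follows the independent race: the response is inhibited iff
`ssd + ssrt_true < t_go` with `t_go` ex-Gaussian, optionally defeated by a
trigger failure.  "SSD at 50% stopping" is operationalised as the *mean SSD
over stop trials in the second half of sub-blocks* (the tracking
estimator); the final-SSD alternative is available via
`SSTConfig(ssd_estimator="last")`.  Median go RT is taken over the same
second-half window for internal consistency, and SSRT is their difference.
For a perfectly deterministic participant the ±step staircase oscillates
between the two grid points bracketing the true threshold, so the tracking
estimator carries a worst-case bias of step/2 (25 ms); with stochastic go
RTs the estimator is unbiased in expectation, and the suite verifies mean
recovery within ±25 ms of a 250 ms ground truth over 200 simulated
participants.  Trigger failures bias estimated SSRT upward, as race-model
theory predicts; estimating trigger-failure rates is out of scope.

## Statistical conventions

Sample (n−1) variances and two-tailed p-values throughout.  Cronbach's α
uses the item-variance form on complete cases only (the 8-item matrix keeps
sessions with all inhibitory trials valid; `k=6` is the explicit fallback
that keeps more participants).  Independent-groups Cohen's *d* uses the
pooled SD; the paired convention is *d* = *t*/√n — both verified in tests
against printed summary-statistic/effect-size pairs (0.64 and 0.87).
Welch's t accepts raw samples or (M, SD, n) summaries.  The ANOVA routines
implement textbook balanced sums of squares (mixed between×within, one-way
RM, and two-way fully-within with each effect tested against its own
effect-by-subject interaction) with partial η² = SS_effect /
(SS_effect + SS_error) and listwise deletion; no sphericity correction is
applied (two-level contrasts are unaffected; a known limitation for
three-level factors).  Bootstrap CIs are percentile-method with B = 1000
default, resampling participants (pairs/rows), fully seeded and therefore
bit-reproducible; percentile intervals are known to undercover slightly at
small n, which the coverage test brackets rather than hides.  Partial
correlation residualises on the controls (with intercept) and uses
df = n − 2 − k.  The age-trend comparison fits linear then quadratic OLS on
centred age and reports the ΔR² increment F-test.

## Problem sizes

Default verification runs use sizes at which Monte-Carlo error is small
relative to the asserted tolerances while the whole suite stays fast:
10,000 draws for the uniformity goodness-of-fit (α = 0.01), 200–500
sessions for accuracy-convergence checks, n = 200 per group for profile
calibration (±5 pp at a per-participant SD of ~25 pp), 400 participants ×
3 replicates for the attenuation oracle, 200 participants for SSRT
recovery, and a 2000-stop-trial staircase for the 50% convergence figure.
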