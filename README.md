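# ecitt

A Python toolkit for an early-childhood inhibitory touchscreen task and its
validation statistics — for developmental and lifespan researchers who need a
response-inhibition measure that keeps the same structure from toddlerhood to
old age, and for methodologists studying the psychometrics of difference
scores.

The task shows a target ("smiley") in one of two screen locations.  It
appears in one location on 75% of trials (*prepotent* trials), building up a
dominant motor response, and switches to the other location on 25%
(*inhibitory* trials), which then require suppressing that response.  The
toolkit implements everything around this design that does not need a
touchscreen:

- **Sequencing** — constrained pseudo-random trial order (exact 24/8 split
  per 32-trial block, 3-trial prepotent lead-in, at most 5 prepotent and
  2 inhibitory trials in a row), sampled *exactly uniformly* over the valid
  arrangements via dynamic-programming completion counts; plus top/bottom
  counterbalancing that persists across longitudinal visits.
- **Simulation** — generative participants with condition-dependent accuracy,
  ex-Gaussian reaction times with inhibitory slowing, anticipations,
  distractions and invalid trials; cohorts with between-subject heterogeneity
  and a latent longitudinal trait; and an independent horse-race stopping
  process for the stop-signal task.
- **Scoring** — the cleaning pipeline (RT floor 300 ms toddler / 200 ms
  adult, 5000 ms ceiling for RT analyses, first-trial discard, validity
  codes) and the inhibition scores

  ```
  AccD  = %correct(prepotent) − %correct(inhibitory)      [percentage points]
  AccD* = AccD / (prepotent proportion correct)           [adjusted AccD]
  RTD   = median RT(inhibitory) − median RT(prepotent)    [ms, correct trials]
  ```

  with strict >60% prepotent-accuracy inclusion.
- **Psychometrics & statistics** — Cronbach's α on binary trial matrices,
  Cohen's κ, Welch and paired *t* (pooled-SD *d*; paired *d* = *t*/√n),
  balanced mixed and repeated-measures ANOVA with partial η², seeded
  percentile-bootstrap CIs for Pearson and partial correlations, and
  hierarchical linear/quadratic age-trend regression.
- **Stop-signal engine** — sub-block trial structure (12 go + 4 stop per 16),
  ±50 ms one-up/one-down SSD staircase, and SSRT = median go RT − SSD(50%)
  over the second half of sub-blocks.

## Worked example

```python
from ecitt.fixtures import worked_example_session
from ecitt import score_session

sc = score_session(worked_example_session())
print(sc.prepotent.pct_correct, sc.inhibitory.pct_correct)
print(sc.scores.accd, sc.scores.accd_adjusted, sc.scores.included)
```

prints

```
62.5 50.0
12.5 20.0 True
```

A toddler 62.5% correct on prepotent trials and 50% on inhibitory trials has
AccD = 12.5 — the same raw score as a near-ceiling toddler at 100% vs 87.5% —
but the adjusted score (12.5 / 0.625 = 20.0) reveals the weaker prepotency
behind it.  The `examples/` directory holds five short narrative scripts, one
per capability: sequence generation, simulate-and-score, longitudinal
stability, stop-signal SSRT recovery, and the lifespan U-shaped age trend.
Each builds its own input, runs the method and explains the numbers it
prints.  A thin CLI (`ecitt generate|simulate|score|analyze|sst|fixtures`)
wraps the same functions for shell pipelines.

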