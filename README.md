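# antisaccade

Race-to-threshold modelling and tachometric analysis of urgent
antisaccade behavior.

## The problem

In the antisaccade task a salient cue appears and the subject must look
away from it — a direct conflict between an involuntary, stimulus-driven
(exogenous) drive toward the cue and a voluntary, goal-driven (endogenous)
plan away from it.  Mean reaction time and overall error rate confound
these processes.  Making the task *urgent* — giving the go signal a gap of
0–350 ms **before** the cue, with a 450-ms response deadline — resolves
them: plotting the probability of a correct antisaccade against the raw
processing time, rPT = RT − gap (how long the cue was actually visible),
yields the **tachometric curve**.  For this task it has a unique shape: a
chance floor at short rPTs (guesses), a deep dip to near 0% correct at
rPT ≈ 100–140 ms (the **vortex**, where the eyes are captured by the cue),
and an extremely fast rise to a near-perfect asymptote.

This package is for psychophysicists and computational neuroscientists who
want to simulate, analyze, and fit this class of behavior.  It provides:

- `race_model` — a trial-level simulator: two motor plans r_C and r_A race
  to a 1000-AU threshold (1-ms steps, 20-ms efferent delay).  During the
  **exogenous response interval (ERI)** that follows cue detection, the
  anti plan halts (gain `g_eri ≤ 0`) while the cue plan halts for
  `delta_eri` ms and then accelerates at `a_ex` — the mechanism of
  oculomotor capture; afterwards the endogenous signal accelerates the
  anti plan (`a_end`) and decelerates the cue plan (`d_end`), except on
  lapse trials.  Restricted variants (`accel_only`, `halt_only`) isolate
  each mechanism.
- `tachometrics` — sliding-bin curve estimation (15-ms bins every 1 ms),
  the dual-sigmoid fit v(x) = max(s_L, s_R, 0) with the left asymptote
  pinned at chance, eight curve features, and trial-level bootstrap CIs.
- `indiv_diffs` — partial Pearson/Spearman correlations and
  luminance-adjusted regression for individual-differences analyses.
- `model_fitting` — fits the 15-parameter model to trial tables by summed
  mean-absolute error over per-gap RT distributions and the tachometric
  curve, via a shrinking-box multi-start random search, with the motor
  parameters shared across luminance conditions.
- `synthetic_experiment` — full synthetic cohorts with the study design
  (6 participants × 30 blocks × 150 trials, 11 gaps, 3 interleaved cue
  luminances).
- a CLI: `antisaccade simulate | tachometric | features | bootstrap |
  fit | synth | report`.

Pooled-data parameter values for three cue luminances ship as
`antisaccade.POOLED_PARAMS`.

## Worked example

```python
import numpy as np
from antisaccade import (POOLED_PARAMS, simulate_dataset,
                         compute_tachometric, fit_tachometric,
                         extract_features, rise_span)

gaps = [0, 75, 100, 125, 150, 175, 200, 250, 350]
trials = simulate_dataset({"high": POOLED_PARAMS["high"]}, gaps,
                          n_trials=150_000, seed=0)
trials = trials[trials.outcome_class != "no_response"]

curve = compute_tachometric(trials)              # 15-ms bins, 1-ms steps
fit = fit_tachometric(curve, seed=0)             # v(x), A_L fixed at 0.5
feats = extract_features(fit, (-100, 400))
print(f"vortex time    {feats.vortex_time:.0f} ms")
print(f"vortex depth   {feats.vortex_depth:.3f}")
print(f"centerpoint    {feats.centerpoint:.0f} ms")
print(f"asymptote      {feats.asymptote:.3f}")
print(f"rise 0.25-0.75 {rise_span(fit, 0.25, 0.75):.0f} ms")
```

prints

```
vortex time    107 ms
vortex depth   0.079
centerpoint    141 ms
asymptote      0.996
rise 0.25-0.75 22 ms
```

Read: with the bright cue, captured (incorrect) saccades are almost
certain when the cue has been visible for ≈ 107 ms at saccade onset
(performance drops to ≈ 0.08 correct, far below the 0.5 chance floor);
by ≈ 141 ms of cue viewing the voluntary process has won back half the
distance to the ≈ 0.996 asymptote, and the transition from mostly-captured
to mostly-correct takes only ≈ 22 ms of extra viewing time.

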