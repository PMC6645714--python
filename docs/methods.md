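# Methods

## The task and the model

In the compelled antisaccade task the go signal (fixation offset) precedes
the cue by a gap of 0–350 ms, so the participant must begin programming a
saccade before knowing which direction is correct, and must respond within
450 ms.  The behavioral readout is the tachometric curve: the probability
of a correct (anti) saccade as a function of raw processing time
rPT = RT − gap, the time the cue was actually visible before the saccade.
For this task the curve has a characteristic non-monotonic shape: chance
performance at short rPTs (guesses), a deep dip below chance near
rPT ≈ 100–140 ms (the "vortex", where saccades are captured by the cue),
and a very fast rise toward a near-perfect asymptote.

The simulator is an accelerated race-to-threshold model.  Two scalar motor
plans, `r_C` toward the cue and `r_A` toward the opposite location, start
at zero and integrate their build-up rates each millisecond; the first to
reach 1000 AU triggers a saccade 20 ms later (efferent delay).  A trial has
three epochs:

1. **Motor epoch.**  After a go afferent delay (Gaussian, sub-20-ms draws
   rejected) both plans rise linearly with initial rates drawn from a
   bivariate Gaussian (mean `mu_b`, SD `sigma_b`, correlation `rho_b`;
   strongly negative `rho_b` means one plan usually dominates).  Negative
   activity values are floored at zero each step, so a plan with a negative
   rate simply waits at zero.
2. **Exogenous response interval (ERI).**  Cue detection occurs a cue
   afferent delay after cue onset (Gaussian, floored likewise); from then
   on, for a Gaussian-distributed duration (`mu_eri`, negatives clipped to
   zero), the competition is biased toward the cue: the anti plan's rate is
   scaled by `g_eri ≤ 0` (halted or suppressed) for the whole interval,
   while the cue plan halts for the first `delta_eri` ms, then instantly
   recovers its rate and gains `a_ex` per ms until the interval ends.
3. **Endogenous epoch.**  Once the cue is interpreted, the anti plan
   recovers its rate and accelerates at `a_end` while the cue plan's rate
   falls by `|d_end|` per ms.  With probability `lapse` this update never
   arrives and both plans keep their ERI-final rates.

The 15 per-luminance parameters (with the five motor parameters shared
across luminance conditions) ship with the pooled-data values for the
high, medium and low cue-luminance conditions; dimmer cues mainly slow and
blur cue detection (`mu_cue_aff`, `sigma_cue_aff`) and weaken the
exogenous push (`a_ex`).

### Numerical conventions

The engine samples a piecewise-linear build-up schedule defined on the
absolute trial clock at the end of each 1-ms step: rates first, then
integration, then the zero floor, then the threshold test.  This is
equivalent to the per-step recurrences whenever the event times (build-up
onset, cue detection, ERI boundaries) fall on the step grid, which is
always the case for the deterministic configurations used as oracles; for
stochastic event times the continuous schedule is the defining convention.
If both plans cross in the same step the larger value wins and exact ties
are resolved uniformly at random.  If the go afferent delay has not
elapsed when the ERI begins, plans stay at zero until onset, and the
epoch-specific rate formulas remain defined on the absolute clock
thereafter (a rare configuration requiring the go delay to exceed
gap + cue delay + ERI).  Trials with no crossing by 5000 ms are flagged
unresponsive and excluded from analyses; trials beyond the 450-ms deadline
are flagged but retained by default.  An independently written scalar
step-integrator (in the test suite) reproduces the engine trial-for-trial
on integer-valued event times, for all three model variants.

## Tachometric estimation and fitting

Curves use 15-ms bins centered on a 1-ms grid (a bin covers
center ± 7 ms inclusive); the proportion correct per bin is invariant to
the common normalization of the correct/incorrect frequency functions.
Each curve is summarized by v(x) = max(s_L(x), s_R(x), 0), two logistic
branches with a shared floor B: s_L falls from the fixed chance asymptote
A_L = 0.5 toward B with midpoint C_L and width D_L; s_R rises from B to
A_R with midpoint C_R and width D_R.  Fitting minimizes the mean absolute
error at occupied bin centers by multi-start Nelder–Mead (data-anchored
heuristic starts plus random starts, followed by polish restarts of the
incumbent, which guards against collapsed simplices on this multimodal
surface).

Two estimator choices matter and are deliberate defaults, both
configurable:

- **Fitting window.**  Bins within a fixed [−100, 400] ms rPT window enter
  the objective.  Simulated datasets contain a long sparse tail of slow
  trials whose nearly empty bins otherwise dominate the error with pure
  binomial noise; with the window, desk-scale fits are stable.
- **Count weighting.**  Each bin's absolute error is weighted by its trial
  count, reflecting the binomial precision of the bin.  With unweighted
  errors the location of the optimizer's global basin flips between
  datasets drawn from identical conditions (fitted vortex depth varied by
  a factor of four across seeds); with count weighting the fitted features
  are reproducible (vortex depth SD ≈ 0.006 at n = 150k).

The eight features (asymptote, vortex depth and time, extreme slopes,
left edge, centerpoint, mean perceptual accuracy over rPT ∈ [0, 250]) are
read off a 1-ms grid; the midway crossings use the grid point nearest the
valley on the falling branch and the first crossing past the valley on the
rising branch.  Flat branches yield NaN and are flagged.  Confidence
intervals are trial-level percentile bootstraps: resample trials with
replacement, recompute the curve, refit (warm-started at the point fit
plus random restarts), re-extract; 2.5/97.5 percentiles of the resulting
distributions.  Failed replicate fits are dropped and counted, with a
warning above 5%.

## Model fitting

The fit objective sums mean absolute errors over binned target functions:
per luminance, the RT histograms of correct and of incorrect trials at
each gap (10-ms bins over [0, 600] ms, masses normalized by the
luminance's trial count) plus the tachometric curve.  Simulated trials use
gap frequencies matched to the data and common random numbers across the
candidates of a search round.  The search itself samples candidates
uniformly in a box, keeps the best, and shrinks every box dimension by 0.7
per round, clipped to the original bounds; independent multi-starts guard
against local minima, and a joint multi-luminance fit shares the motor
block by construction.  The packaged default schedule (8 starts × 40
rounds × 60 candidates at 2×10⁴ simulated trials per evaluation) is sized
for a workstation run of some hours; the recovery study in the test suite
uses a desk-scale schedule (3 × 20 × 30 at 6×10³), which recovers the cue
afferent-delay mean within ±10% while weakly identified parameters
(`rho_b`, `sigma_eri`, and at this scale also `a_ex`) remain loosely
constrained — their recovery should be read as order-of-magnitude only.

## Synthetic experiments

The cohort generator emulates the study design: 6 participants × 30 blocks
× 150 trials, gap drawn uniformly from {−200, −100, 0, 75, 100, 125, 150,
175, 200, 250, 350} ms, cue side and one of three luminances uniform per
trial, 450-ms deadline.  Participant heterogeneity is multiplicative
Gaussian jitter (default SD 10% per parameter) around a template, with the
motor block jittered once per participant so it stays shared across that
participant's conditions; clipping restores parameter invariants.  Easy
delayed trials (gap < 0) are outside the mechanistic model and are emulated
statistically — correct with probability 0.992 and RT drawn from a
lognormal (median 280 ms, log-SD 0.25), yielding the long processing times
characteristic of non-urgent responding.  This emulation supports pipeline
plumbing and mean-accuracy summaries only; nothing mechanistic should be
concluded from delayed trials.  Under this design the expected number of
urgent high-luminance trials per participant is 4500·(9/11)·(1/3) ≈ 1227,
and the expected total high-luminance count is 1500.

What the generator does not emulate: session/block structure effects
(practice, fatigue), express-saccade idiosyncrasies, microsaccades or
fixation-period dynamics, and any non-stationarity of lapse rates.
Passing tests on synthetic cohorts therefore demonstrate internal
consistency of the pipeline under the model's assumptions, not validity
for any particular empirical dataset.

## Known quantitative limitations

With the packaged pooled-data parameters the simulated high-luminance
curve has its fitted minimum at rPT ≈ 107 ms with depth ≈ 0.08, rises from
0.25 to 0.75 in ≈ 22 ms and from 0.10 to 0.90 in ≈ 48 ms, and the
low-luminance curve has its minimum at ≈ 160 ms with depth ≈ 0.39 (stable
across seeds at n = 150k trials).  The dip is somewhat shallower and the
rise somewhat slower than the sharpest published empirical estimates for
this task family; the residual correct responses inside the vortex window
are pre-detection guesses leaking in through slow cue-detection draws and
fast correct escapes in which the anti plan sits near threshold at
detection, survives the halt, and crosses immediately after the ERI.  Both
are intrinsic to the stated dynamics under the documented conventions.
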