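"""Synthetic cohort generator emulating the compelled-antisaccade study
design: six participants, 30 blocks of 150 trials, three interleaved cue
luminances, eleven gap values (two of them negative, i.e. easy delayed
trials), and a 450-ms response deadline.

Urgent trials (gap >= 0) are produced mechanistically by the race model.
Easy delayed trials (gap < 0) are emulated statistically — near-ceiling
accuracy with long processing times — because the mechanistic model covers
urgent trials only; their RT model is a declared lognormal convention, not
a mechanistic claim.  Participant heterogeneity is introduced by
multiplicative Gaussian jitter of a template parameter set; the motor
block is jittered once per participant so it stays shared across that
participant's luminance conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import LuminanceParams, ModelVariant, POOLED_PARAMS, SimConstants
from .race_model import TRIAL_COLUMNS, _simulate_condition
from .model_fitting import MOTOR_PARAMS, CONDITION_PARAMS

__all__ = ["ExperimentDesign", "ParticipantSpec", "make_cohort",
           "generate_experiment"]

DEFAULT_GAPS_MS = (-200.0, -100.0, 0.0, 75.0, 100.0, 125.0, 150.0, 175.0,
                   200.0, 250.0, 350.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design constants of one synthetic experiment.

    ``fixation_ms`` is carried as metadata only (the model clock starts at
    the go signal).  Delay trials are drawn with the same per-trial
    probability as every other gap; ``delay_correct_rate`` and the
    lognormal RT parameters define their statistical emulation.
    """

    n_participants: int = 6
    n_blocks: int = 30
    trials_per_block: int = 150
    gaps_ms: tuple = DEFAULT_GAPS_MS
    luminances: tuple = ("high", "medium", "low")
    rt_deadline_ms: float = 450.0
    fixation_ms: tuple = (150.0, 250.0, 350.0)
    delay_correct_rate: float = 0.992
    delay_rt_meanlog: float = math.log(280.0)
    delay_rt_sdlog: float = 0.25

    def __post_init__(self):
        if self.n_participants <= 0 or self.trials_per_block <= 0:
            raise ValueError("participant and trial counts must be positive")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be nonnegative")
        if len(self.gaps_ms) == 0:
            raise ValueError("gap set must be non-empty")

    @property
    def n_trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class ParticipantSpec:
    """Parameter sets for one (real or template) participant.

    ``jitter_sd`` maps parameter names to multiplicative Gaussian SDs used
    when this spec serves as a cohort template; a spec emitted by
    :func:`make_cohort` has its jitter zeroed and records its provenance.
    """

    params_by_luminance: dict
    jitter_sd: dict = field(default_factory=dict)
    participant: str = "template"
    seed: int | None = None

    def __post_init__(self):
        if not self.params_by_luminance:
            raise ValueError("params_by_luminance must be non-empty")


DEFAULT_JITTER_SD = {name: 0.10 for name in MOTOR_PARAMS + CONDITION_PARAMS}

#: clip ranges restoring parameter invariants after jitter
_CLIP = {
    "sigma_b": (0.0, np.inf), "sigma_go_aff": (0.0, np.inf),
    "sigma_cue_aff": (0.0, np.inf), "sigma_eri": (0.0, np.inf),
    "rho_b": (-1.0, 1.0), "lapse": (0.0, 1.0), "g_eri": (-np.inf, 0.0),
    "d_end": (-np.inf, 0.0), "a_end": (0.0, np.inf), "delta_eri": (0.0, np.inf),
}


def _jitter_value(value: float, sd: float, name: str,
                  rng: np.random.Generator) -> float:
    out = value * (1.0 + sd * rng.standard_normal()) if sd > 0 else value
    lo, hi = _CLIP.get(name, (-np.inf, np.inf))
    return float(np.clip(out, lo, hi))


def make_cohort(design: ExperimentDesign,
                template: ParticipantSpec | None = None,
                seed: int | np.random.Generator = 0) -> list[ParticipantSpec]:
    """Draw per-participant parameter sets by jittering a template.

    Motor parameters are jittered once per participant and shared across
    luminances; condition parameters are jittered per luminance.
    Deterministic given ``seed``.
    """
    if template is None:
        template = ParticipantSpec(params_by_luminance=dict(POOLED_PARAMS),
                                   jitter_sd=dict(DEFAULT_JITTER_SD))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jit = template.jitter_sd
    cohort = []
    for i in range(design.n_participants):
        first = next(iter(template.params_by_luminance.values()))
        motor = {m: _jitter_value(getattr(first, m), jit.get(m, 0.0), m, rng)
                 for m in MOTOR_PARAMS}
        by_lum = {}
        for lum, base in template.params_by_luminance.items():
            cond = {c: _jitter_value(getattr(base, c), jit.get(c, 0.0), c, rng)
                    for c in CONDITION_PARAMS}
            by_lum[lum] = LuminanceParams(**motor, **cond)
        cohort.append(ParticipantSpec(params_by_luminance=by_lum,
                                      jitter_sd={}, participant=f"P{i + 1}",
                                      seed=None))
    return cohort


def _emulate_delay_trials(gaps: np.ndarray, design: ExperimentDesign,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Statistical stand-in for easy (cue-before-go) trials."""
    n = gaps.size
    correct = rng.random(n) < design.delay_correct_rate
    rt = np.exp(design.delay_rt_meanlog + design.delay_rt_sdlog * rng.standard_normal(n))
    cue_left = rng.random(n) < 0.5
    cue_side = np.where(cue_left, "left", "right")
    anti_side = np.where(cue_left, "right", "left")
    return pd.DataFrame({
        "gap_ms": gaps,
        "cue_side": cue_side,
        "choice_side": np.where(correct, anti_side, cue_side),
        "correct": correct,
        "rt_ms": rt,
        "rpt_ms": rt - gaps,
        "deadline_exceeded": rt > design.rt_deadline_ms,
        "outcome_class": "easy",
        "sim_b_c0": np.nan, "sim_b_a0": np.nan, "sim_go_delay": np.nan,
        "sim_cue_detect_time": np.nan, "sim_eri_duration": np.nan,
        "sim_lapse": False,
    })


def generate_experiment(cohort: list[ParticipantSpec],
                        design: ExperimentDesign = ExperimentDesign(),
                        consts: SimConstants = SimConstants(),
                        seed: int | np.random.Generator = 0,
                        variant: ModelVariant = ModelVariant.FULL) -> pd.DataFrame:
    """Generate a full synthetic experiment as one trial table.

    Gap, luminance, and cue side are sampled independently and uniformly
    per trial.  Urgent trials run through the race model with the
    participant's parameters; delay trials use the statistical emulation.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gaps_all = np.asarray(design.gaps_ms, dtype=float)
    n_per = design.n_trials_per_participant
    frames = []
    for spec in cohort:
        if n_per == 0:
            continue
        lums = list(spec.params_by_luminance)
        gap_idx = rng.integers(0, gaps_all.size, size=n_per)
        lum_idx = rng.integers(0, len(lums), size=n_per)
        trial_gaps = gaps_all[gap_idx]
        parts = []
        for j, lum in enumerate(lums):
            m_urgent = (lum_idx == j) & (trial_gaps >= 0)
            m_delay = (lum_idx == j) & (trial_gaps < 0)
            if m_urgent.any():
                sub = _simulate_condition(spec.params_by_luminance[lum],
                                          trial_gaps[m_urgent], consts, variant, rng)
                sub["deadline_exceeded"] = (
                    (sub["outcome_class"] != "no_response")
                    & (sub["rt_ms"] > design.rt_deadline_ms))
                sub.insert(0, "luminance", lum)
                sub.index = np.flatnonzero(m_urgent)
                parts.append(sub)
            if m_delay.any():
                sub = _emulate_delay_trials(trial_gaps[m_delay], design, rng)
                sub.insert(0, "luminance", lum)
                sub.index = np.flatnonzero(m_delay)
                parts.append(sub)
        table = pd.concat(parts).sort_index()
        table.insert(0, "participant", spec.participant)
        frames.append(table.reset_index(drop=True))
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            TRIAL_COLUMNS,
            [str, str, float, str, str, bool, float, float, bool, str,
             float, float, float, float, float, bool])})
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
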