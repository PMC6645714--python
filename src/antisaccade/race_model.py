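"""Accelerated race-to-threshold simulator for the compelled antisaccade task.

Two motor plans, one toward the cue (``rC``) and one toward the opposite
(anti) location (``rA``), rise from zero toward a fixed threshold; the first
to cross it triggers the saccade after a short efferent delay.  A trial
unfolds in three epochs:

1. After a go-signal afferent delay both plans grow linearly at initial
   build-up rates drawn from a correlated bivariate Gaussian.
2. Once the cue is detected (an afferent delay after cue onset) the
   exogenous response interval (ERI) begins: the anti plan's build-up rate is
   scaled by ``g_eri`` (halted or suppressed) for the whole ERI, while the
   cue plan halts for the first ``delta_eri`` ms, then instantly recovers its
   initial rate and gains ``a_ex`` per ms until the ERI ends.
3. After the ERI the cue is interpreted: the anti plan recovers its initial
   rate and accelerates at ``a_end`` while the cue plan decelerates at
   ``d_end``.  On lapse trials (probability ``lapse``) this endogenous update
   never arrives and both plans keep their ERI-final rates.

Negative values of ``rC``/``rA`` are reset to zero at every step.  Within a
step, build-up rates are updated first, the rates are then integrated into
``rC``/``rA``, and the threshold is checked last; equivalently, the engine
samples the piecewise-linear build-up schedule at step ends on the absolute
trial clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import LuminanceParams, ModelVariant, SimConstants

__all__ = [
    "TrialRecord",
    "sample_build_up_rates",
    "sample_afferent_delay",
    "sample_eri_duration",
    "simulate_trial",
    "simulate_dataset",
    "TRIAL_COLUMNS",
]

#: canonical trial-table schema (latent diagnostics carry a ``sim_`` prefix)
TRIAL_COLUMNS = [
    "participant", "luminance", "gap_ms", "cue_side", "choice_side",
    "correct", "rt_ms", "rpt_ms", "deadline_exceeded", "outcome_class",
    "sim_b_c0", "sim_b_a0", "sim_go_delay", "sim_cue_detect_time",
    "sim_eri_duration", "sim_lapse",
]

RT_DEADLINE_MS = 450.0


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial with latent diagnostics.

    ``rpt`` (raw processing time) is the cue-viewing time ``rt - gap``;
    ``cue_detect_time`` is measured from cue onset.  ``outcome_class`` is
    ``guess`` (threshold crossed before cue detection), ``captured``
    (incorrect saccade after detection), ``informed`` (correct saccade after
    detection) or ``no_response``.
    """

    gap: float
    cue_side: str
    choice_side: str
    correct: bool
    rt: float
    rpt: float
    deadline_exceeded: bool
    b_c0: float
    b_a0: float
    go_delay: float
    cue_detect_time: float
    eri_duration: float
    lapse: bool
    outcome_class: str


# ---------------------------------------------------------------------------
# elementary samplers

def sample_build_up_rates(params: LuminanceParams, rng: np.random.Generator,
                          size: int | None = None):
    """Draw initial build-up rates (b_c0, b_a0) for the two plans.

    The pair comes from a bivariate Gaussian with common mean ``mu_b``, SD
    ``sigma_b`` and correlation ``rho_b``; draws may be negative.
    """
    n = 1 if size is None else int(size)
    z = rng.standard_normal((n, 2))
    rho = params.rho_b
    # Cholesky factor of [[1, rho], [rho, 1]]
    b_c = params.mu_b + params.sigma_b * z[:, 0]
    b_a = params.mu_b + params.sigma_b * (rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1])
    if size is None:
        return float(b_c[0]), float(b_a[0])
    return b_c, b_a


def sample_afferent_delay(mu: float, sigma: float, floor: float,
                          rng: np.random.Generator, size: int | None = None,
                          max_rounds: int = 1000):
    """Draw Gaussian afferent delays, rejecting (not clipping) values below
    ``floor``.

    Raises
    ------
    ValueError
        If the Gaussian places essentially no mass at or above the floor
        (e.g. ``sigma == 0`` with ``mu < floor``), detected after
        ``max_rounds`` rejection rounds.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    n = 1 if size is None else int(size)
    if sigma == 0.0:
        if mu < floor:
            raise ValueError(
                f"degenerate afferent delay mu={mu} below floor={floor} is unsatisfiable")
        out = np.full(n, float(mu))
        return float(out[0]) if size is None else out
    out = mu + sigma * rng.standard_normal(n)
    bad = out < floor
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            raise ValueError(
                f"afferent delay rejection did not terminate (mu={mu}, sigma={sigma}, "
                f"floor={floor}); distribution has negligible mass above the floor")
        k = int(bad.sum())
        out[bad] = mu + sigma * rng.standard_normal(k)
        bad = out < floor
    return float(out[0]) if size is None else out


def sample_eri_duration(mu: float, sigma: float, rng: np.random.Generator,
                        size: int | None = None):
    """Draw Gaussian ERI durations with negative values reset to zero."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    n = 1 if size is None else int(size)
    out = np.maximum(mu + sigma * rng.standard_normal(n), 0.0)
    if sigma == 0.0:
        out = np.full(n, max(float(mu), 0.0))
    return float(out[0]) if size is None else out


# ---------------------------------------------------------------------------
# vectorized race engine

def _run_races(b_c0, b_a0, t_on, t_detect, eri_dur, lapse_mask,
               params: LuminanceParams, consts: SimConstants,
               variant: ModelVariant, rng: np.random.Generator):
    """Integrate many races at once; returns (cross_time, anti_wins, responded).

    All array arguments have one entry per trial.  ``t_detect`` is on the
    absolute trial clock (gap + cue afferent delay).  The per-step update
    order is: build-up rates first, integration second, zero floor third,
    threshold check last.
    """
    n = b_c0.size
    dt = consts.dt
    thr = consts.threshold
    cue_perturbed = variant is not ModelVariant.HALT_ONLY
    anti_halted = variant is not ModelVariant.ACCEL_ONLY

    eri_start = t_detect
    eri_end = eri_start + eri_dur
    if cue_perturbed:
        accel_start = eri_start + np.minimum(params.delta_eri, eri_dur)
        b_c_end = b_c0 + params.a_ex * np.maximum(eri_dur - params.delta_eri, 0.0)
    else:
        accel_start = eri_end  # no acceleration phase
        b_c_end = b_c0.copy()

    # state for still-active trials, compressed as trials finish
    idx = np.arange(n)
    rC = np.zeros(n)
    rA = np.zeros(n)
    cross_time = np.full(n, np.nan)
    anti_wins = np.zeros(n, dtype=bool)

    state = [b_c0.astype(float), b_a0.astype(float), t_on.astype(float),
             eri_start.astype(float), accel_start.astype(float),
             eri_end.astype(float), b_c_end.astype(float),
             lapse_mask.astype(bool)]

    t = 0.0
    n_steps = int(round(consts.t_max / dt))
    for _ in range(n_steps):
        t += dt
        bc0, ba0, ton, es, as_, ee, bce, lam = state
        started = t > ton
        post = t > ee

        b_c = np.where(started, bc0, 0.0)
        if cue_perturbed:
            b_c = np.where((t > es) & (t <= as_), params.g_eri * bc0, b_c)
            b_c = np.where((t > as_) & (t <= ee), bc0 + params.a_ex * (t - as_), b_c)
        b_c = np.where(post, np.where(lam, bce, bce + params.d_end * (t - ee)), b_c)
        b_c = np.where(started, b_c, 0.0)

        b_a = np.where(started, ba0, 0.0)
        if anti_halted:
            b_a = np.where((t > es) & (t <= ee), params.g_eri * ba0, b_a)
        b_a = np.where(post, np.where(lam, ba0, ba0 + params.a_end * (t - ee)), b_a)
        b_a = np.where(started, b_a, 0.0)

        rC = np.maximum(rC + b_c * dt, 0.0)
        rA = np.maximum(rA + b_a * dt, 0.0)

        done = (rC >= thr) | (rA >= thr)
        if done.any():
            di = idx[done]
            cross_time[di] = t
            c_vals = rC[done]
            a_vals = rA[done]
            wins = a_vals > c_vals
            both = (c_vals >= thr) & (a_vals >= thr)
            ties = both & (a_vals == c_vals)
            if ties.any():
                wins = wins.copy()
                wins[ties] = rng.random(int(ties.sum())) < 0.5
            anti_wins[di] = wins
            keep = ~done
            idx = idx[keep]
            if idx.size == 0:
                break
            rC = rC[keep]
            rA = rA[keep]
            state = [a[keep] for a in state]
    responded = ~np.isnan(cross_time)
    return cross_time, anti_wins, responded


def _simulate_condition(params: LuminanceParams, gaps: np.ndarray,
                        consts: SimConstants, variant: ModelVariant,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one trial per entry of ``gaps`` under a single parameter set.

    Per-trial draws are made in a fixed order (go delay, build-up rates, cue
    delay, ERI duration, lapse, cue side), one array per field.
    """
    if np.any(gaps < 0):
        raise ValueError("mechanistic simulation covers urgent trials (gap >= 0) only")
    n = gaps.size
    go_delay = sample_afferent_delay(params.mu_go_aff, params.sigma_go_aff,
                                     consts.afferent_floor, rng, size=n)
    b_c0, b_a0 = sample_build_up_rates(params, rng, size=n)
    cue_delay = sample_afferent_delay(params.mu_cue_aff, params.sigma_cue_aff,
                                      consts.afferent_floor, rng, size=n)
    eri_dur = sample_eri_duration(params.mu_eri, params.sigma_eri, rng, size=n)
    lapse_mask = rng.random(n) < params.lapse
    cue_left = rng.random(n) < 0.5

    t_detect = gaps + cue_delay
    cross_t, anti_wins, responded = _run_races(
        b_c0, b_a0, go_delay, t_detect, eri_dur, lapse_mask,
        params, consts, variant, rng)

    rt = cross_t + consts.efferent_delay
    rpt = rt - gaps
    guess = responded & (cross_t <= t_detect)
    outcome = np.where(responded,
                       np.where(guess, "guess",
                                np.where(anti_wins, "informed", "captured")),
                       "no_response")
    cue_side = np.where(cue_left, "left", "right")
    anti_side = np.where(cue_left, "right", "left")
    choice = np.where(responded, np.where(anti_wins, anti_side, cue_side), "")
    return pd.DataFrame({
        "gap_ms": gaps,
        "cue_side": cue_side,
        "choice_side": choice,
        "correct": anti_wins & responded,
        "rt_ms": rt,
        "rpt_ms": rpt,
        "deadline_exceeded": responded & (rt > RT_DEADLINE_MS),
        "outcome_class": outcome,
        "sim_b_c0": b_c0,
        "sim_b_a0": b_a0,
        "sim_go_delay": go_delay,
        "sim_cue_detect_time": cue_delay,
        "sim_eri_duration": eri_dur,
        "sim_lapse": lapse_mask,
    })


def simulate_trial(params: LuminanceParams, gap: float,
                   consts: SimConstants = SimConstants(),
                   variant: ModelVariant = ModelVariant.FULL,
                   rng: np.random.Generator | None = None) -> TrialRecord:
    """Simulate a single urgent trial and return its :class:`TrialRecord`."""
    if gap < 0:
        raise ValueError("mechanistic simulation covers urgent trials (gap >= 0) only")
    if rng is None:
        rng = np.random.default_rng()
    df = _simulate_condition(params, np.asarray([float(gap)]), consts, variant, rng)
    row = df.iloc[0]
    return TrialRecord(
        gap=float(gap),
        cue_side=row["cue_side"],
        choice_side=row["choice_side"],
        correct=bool(row["correct"]),
        rt=float(row["rt_ms"]),
        rpt=float(row["rpt_ms"]),
        deadline_exceeded=bool(row["deadline_exceeded"]),
        b_c0=float(row["sim_b_c0"]),
        b_a0=float(row["sim_b_a0"]),
        go_delay=float(row["sim_go_delay"]),
        cue_detect_time=float(row["sim_cue_detect_time"]),
        eri_duration=float(row["sim_eri_duration"]),
        lapse=bool(row["sim_lapse"]),
        outcome_class=row["outcome_class"],
    )


def simulate_dataset(params_by_luminance: Mapping[str, LuminanceParams],
                     gaps: Sequence[float], n_trials: int,
                     consts: SimConstants = SimConstants(),
                     variant: ModelVariant = ModelVariant.FULL,
                     seed: int | np.random.Generator = 0,
                     participant: str = "sim") -> pd.DataFrame:
    """Simulate ``n_trials`` urgent trials with gap, cue side and luminance
    each sampled independently and uniformly per trial.

    Returns a trial table in generation order with the canonical schema
    (:data:`TRIAL_COLUMNS`).  Deterministic given ``seed``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    gaps = np.asarray(list(gaps), dtype=float)
    if gaps.size == 0:
        raise ValueError("gap list must be non-empty")
    if np.any(gaps < 0):
        raise ValueError("mechanistic simulation covers urgent trials (gap >= 0) only")
    if not params_by_luminance:
        raise ValueError("params_by_luminance must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lum_keys = list(params_by_luminance)

    gap_idx = rng.integers(0, gaps.size, size=n_trials)
    lum_idx = rng.integers(0, len(lum_keys), size=n_trials)
    trial_gaps = gaps[gap_idx]

    parts = []
    for j, key in enumerate(lum_keys):
        mask = lum_idx == j
        if not mask.any():
            continue
        sub = _simulate_condition(params_by_luminance[key], trial_gaps[mask],
                                  consts, variant, rng)
        sub.insert(0, "luminance", key)
        sub.index = np.flatnonzero(mask)
        parts.append(sub)
    out = pd.concat(parts).sort_index()
    out.insert(0, "participant", participant)
    return out.reset_index(drop=True)[TRIAL_COLUMNS]
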