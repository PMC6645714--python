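"""Fitting the 15-parameter race model to behavioral trial tables.

The objective mirrors the quantities a fit must reproduce: for each
luminance condition, the RT distributions of correct and incorrect trials
at each gap, plus the tachometric curve.  Each term contributes the mean
absolute error between observed and simulated binned functions, and the
total error is their sum.  The search is a shrinking-box iterated random
search: candidates are sampled uniformly in a box around the incumbent,
the best is kept, and the box volume contracts by a fixed factor each
round; several independent starts guard against local minima.  The five
motor parameters (build-up-rate distribution and go afferent delay) can be
shared across luminance conditions, since all trials are identical up to
cue presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .params import LuminanceParams, ModelVariant, SimConstants
from .race_model import _simulate_condition
from .tachometrics import TachCurve, compute_tachometric

__all__ = [
    "TargetSet", "SearchConfig", "FitResult",
    "MOTOR_PARAMS", "CONDITION_PARAMS", "PARAM_ORDER",
    "build_targets", "objective", "fit_model",
]

#: parameters describing pure motor performance (shared across luminances)
MOTOR_PARAMS = ("mu_b", "sigma_b", "rho_b", "mu_go_aff", "sigma_go_aff")
#: parameters that may vary with cue luminance
CONDITION_PARAMS = ("mu_cue_aff", "sigma_cue_aff", "mu_eri", "sigma_eri",
                    "g_eri", "delta_eri", "a_ex", "d_end", "a_end", "lapse")
PARAM_ORDER = MOTOR_PARAMS + CONDITION_PARAMS

DEFAULT_RT_EDGES = np.arange(0.0, 601.0, 10.0)


@dataclass(frozen=True)
class TargetSet:
    """Binned target functions for one or more luminance conditions.

    ``rt_hists[lum][gap]`` holds a pair of per-bin trial-fraction arrays
    (correct, incorrect) over ``rt_edges``; fractions are relative to that
    luminance's total trial count, so the masses of all cells of a
    luminance sum to (at most) one.  ``curves[lum]`` is the observed
    tachometric curve and ``gap_freq[lum]`` the observed gap frequencies
    used to match simulated sampling.
    """

    rt_edges: np.ndarray
    rt_hists: dict
    curves: dict
    gap_freq: dict
    n_trials: dict

    @property
    def luminances(self):
        return list(self.curves)


@dataclass(frozen=True)
class SearchConfig:
    """Shrinking-box search schedule.

    ``shrink`` is the per-round linear contraction factor of every box
    dimension; ``n_sim`` the number of simulated trials per objective
    evaluation.
    """

    n_starts: int = 8
    n_rounds: int = 40
    n_candidates: int = 60
    shrink: float = 0.7
    n_sim: int = 20000


@dataclass(frozen=True)
class FitResult:
    params_by_luminance: dict
    objective: float
    trace: pd.DataFrame
    converged: bool
    seed: int
    n_sim: int


def _hist_masses(rt: np.ndarray, correct: np.ndarray, edges: np.ndarray,
                 n_total: int) -> tuple[np.ndarray, np.ndarray]:
    hc, _ = np.histogram(rt[correct], bins=edges)
    hi, _ = np.histogram(rt[~correct], bins=edges)
    return hc / n_total, hi / n_total


def build_targets(trials: pd.DataFrame,
                  rt_edges: np.ndarray | None = None) -> TargetSet:
    """Deterministically bin a trial table into the fitting targets.

    Requires urgent trials spanning at least two gaps with both outcomes
    present overall.  Unresponsive trials are excluded; empty (gap, outcome)
    cells yield zero histograms.
    """
    edges = DEFAULT_RT_EDGES if rt_edges is None else np.asarray(rt_edges, dtype=float)
    d = trials[(trials["gap_ms"] >= 0) & (trials["outcome_class"] != "no_response")]
    if len(d) == 0:
        raise ValueError("no urgent responded trials to build targets from")
    rt_hists: dict = {}
    curves: dict = {}
    gap_freq: dict = {}
    n_trials: dict = {}
    for lum, cell in d.groupby("luminance", sort=False):
        n = len(cell)
        gaps = np.sort(cell["gap_ms"].unique())
        hists = {}
        for g in gaps:
            sub = cell[cell["gap_ms"] == g]
            hists[float(g)] = _hist_masses(sub["rt_ms"].to_numpy(float),
                                           sub["correct"].to_numpy(bool), edges, n)
        rt_hists[lum] = hists
        curves[lum] = compute_tachometric(cell)
        counts = cell["gap_ms"].value_counts(sort=False)
        gap_freq[lum] = {float(g): counts[g] / n for g in gaps}
        n_trials[lum] = n
    return TargetSet(rt_edges=edges, rt_hists=rt_hists, curves=curves,
                     gap_freq=gap_freq, n_trials=n_trials)


def _curve_mae(obs: TachCurve, sim: TachCurve) -> float:
    """Mean absolute difference of p_correct over bins occupied in both."""
    lo = max(obs.rpt_centers[0], sim.rpt_centers[0])
    hi = min(obs.rpt_centers[-1], sim.rpt_centers[-1])
    if hi < lo:
        return 1.0
    io = slice(int(lo - obs.rpt_centers[0]), int(hi - obs.rpt_centers[0]) + 1)
    is_ = slice(int(lo - sim.rpt_centers[0]), int(hi - sim.rpt_centers[0]) + 1)
    po = obs.p_correct[io]
    ps = sim.p_correct[is_]
    both = np.isfinite(po) & np.isfinite(ps)
    if not both.any():
        return 1.0
    return float(np.mean(np.abs(po[both] - ps[both])))


def objective(params_by_luminance: Mapping[str, LuminanceParams],
              targets: TargetSet, n_sim: int,
              seed: int | np.random.Generator = 0,
              consts: SimConstants = SimConstants(),
              variant: ModelVariant = ModelVariant.FULL) -> float:
    """Summed mean-absolute-error of a parameter set against the targets.

    Simulates ``n_sim`` trials per luminance with gap frequencies matched to
    the observed ones, bins them on the targets' edges, and sums the MAE
    terms (one per RT-histogram cell pair per gap, plus one per tachometric
    curve).  A fixed ``seed`` gives common random numbers across candidate
    evaluations, which stabilizes search comparisons.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = 0.0
    for lum in targets.luminances:
        if lum not in params_by_luminance:
            raise KeyError(f"missing parameters for luminance {lum!r}")
        p = params_by_luminance[lum]
        gf = targets.gap_freq[lum]
        gap_vals = np.array(list(gf))
        probs = np.array(list(gf.values()))
        probs = probs / probs.sum()
        gaps = rng.choice(gap_vals, size=n_sim, p=probs)
        sim = _simulate_condition(p, gaps, consts, variant, rng)
        responded = sim["outcome_class"] != "no_response"
        sim = sim[responded]
        if len(sim) == 0:
            total += 1.0 * (1 + len(targets.rt_hists[lum]))
            continue
        n = len(sim)
        for g, (mc_obs, mi_obs) in targets.rt_hists[lum].items():
            sub = sim[sim["gap_ms"] == g]
            mc, mi = _hist_masses(sub["rt_ms"].to_numpy(float),
                                  sub["correct"].to_numpy(bool),
                                  targets.rt_edges, n)
            total += float(np.mean(np.abs(mc - mc_obs)))
            total += float(np.mean(np.abs(mi - mi_obs)))
        total += _curve_mae(targets.curves[lum], compute_tachometric(sim))
    return total


def _vector_layout(luminances, shared_motor: bool):
    """Names of the free-parameter vector entries, in order."""
    names = []
    if shared_motor:
        names.extend(("shared", m) for m in MOTOR_PARAMS)
        for lum in luminances:
            names.extend((lum, c) for c in CONDITION_PARAMS)
    else:
        for lum in luminances:
            names.extend((lum, f) for f in PARAM_ORDER)
    return names


def _vector_to_params(vec, names, luminances) -> dict:
    by_lum = {lum: {} for lum in luminances}
    shared = {}
    for (scope, pname), v in zip(names, vec):
        if scope == "shared":
            shared[pname] = float(v)
        else:
            by_lum[scope][pname] = float(v)
    return {lum: LuminanceParams(**{**shared, **by_lum[lum]})
            for lum in luminances}


def fit_model(targets: TargetSet,
              bounds: Mapping[str, tuple[float, float]],
              search_config: SearchConfig = SearchConfig(),
              seed: int = 0,
              shared_motor: bool = True,
              consts: SimConstants = SimConstants(),
              variant: ModelVariant = ModelVariant.FULL) -> FitResult:
    """Shrinking-box multi-start random search over the parameter box.

    ``bounds`` maps each of the 15 parameter names to (lo, hi); a
    zero-width bound pins the parameter.  With ``shared_motor`` the five
    motor parameters use a single shared block for all luminances.  Bounds
    may also be keyed ``"<luminance>:<name>"`` to override a condition's
    range.
    """
    luminances = targets.luminances
    names = _vector_layout(luminances, shared_motor)

    def bound_for(scope, pname):
        if scope != "shared" and f"{scope}:{pname}" in bounds:
            lo, hi = bounds[f"{scope}:{pname}"]
        elif pname in bounds:
            lo, hi = bounds[pname]
        else:
            raise KeyError(f"no bounds for parameter {pname!r}")
        if hi < lo:
            raise ValueError(f"invalid bounds for {pname!r}: {(lo, hi)}")
        return float(lo), float(hi)

    full_lo = np.array([bound_for(s, p)[0] for s, p in names])
    full_hi = np.array([bound_for(s, p)[1] for s, p in names])

    cfg = search_config
    trace_rows = []
    best_overall = None

    for start in range(cfg.n_starts):
        srng = np.random.default_rng((seed, start))
        lo, hi = full_lo.copy(), full_hi.copy()
        center = srng.uniform(lo, hi)
        best_vec = center
        best_err = objective(_vector_to_params(best_vec, names, luminances),
                             targets, cfg.n_sim, seed=(seed, start, 0))
        for rnd in range(cfg.n_rounds):
            eval_seed = (seed, start, rnd + 1)  # common random numbers per round
            cands = srng.uniform(lo, hi, size=(cfg.n_candidates, len(names)))
            for vec in cands:
                err = objective(_vector_to_params(vec, names, luminances),
                                targets, cfg.n_sim, seed=eval_seed)
                if err < best_err:
                    best_err = err
                    best_vec = vec
            width = (hi - lo) * cfg.shrink
            lo = np.clip(best_vec - width / 2.0, full_lo, full_hi)
            hi = np.clip(best_vec + width / 2.0, full_lo, full_hi)
            hi = np.maximum(hi, lo)
            trace_rows.append({"start": start, "round": rnd,
                               "best_error": best_err,
                               "volume": float(np.prod(np.maximum(hi - lo, 1e-300)))})
        if best_overall is None or best_err < best_overall[0]:
            best_overall = (best_err, best_vec)

    err, vec = best_overall
    trace = pd.DataFrame(trace_rows)
    converged = bool(len(trace) == 0 or
                     trace.groupby("start")["best_error"].min().min() <= err + 1e-12)
    return FitResult(
        params_by_luminance=_vector_to_params(vec, names, luminances),
        objective=float(err),
        trace=trace,
        converged=converged,
        seed=seed,
        n_sim=cfg.n_sim,
    )
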