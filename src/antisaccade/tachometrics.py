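"""Tachometric-curve estimation, analytical fitting, and feature bootstrap.

The tachometric curve is the probability of a correct choice as a function
of raw processing time (rPT = RT − gap), computed in overlapping 15-ms bins
shifted every 1 ms:

    C(rPT) = f_C(rPT) / (f_C(rPT) + f_I(rPT))

where f_C and f_I are the rPT frequency functions of correct and incorrect
trials normalized by a common factor (which provably cancels in C).  Each
empirical curve is summarized by fitting a continuous function

    v(x) = max(s_L(x), s_R(x), 0)

built from two sigmoids: s_L(x) = B + (A_L − B)/(1 + exp((x − C_L)/D_L))
falls from the chance asymptote A_L = 0.5 (fixed) toward B, and
s_R(x) = B + (A_R − B)/(1 + exp(−(x − C_R)/D_R)) rises from B toward the
late asymptote A_R.  Eight features of the fitted curve quantify perceptual
performance; their confidence intervals come from a trial-level percentile
bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "TachCurve", "VFitParams", "CurveFeatures", "FeatureCI",
    "FitNonConvergence",
    "compute_rpt", "compute_tachometric", "evaluate_v", "fit_tachometric",
    "extract_features", "rise_span", "bootstrap_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "asymptote", "vortex_depth", "vortex_time", "slope_min", "slope_max",
    "left_edge", "centerpoint", "mean_perceptual_accuracy",
)


class FitNonConvergence(RuntimeError):
    """Raised when no optimizer start converges; carries the best-so-far fit."""

    def __init__(self, message: str, best: "VFitParams | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class TachCurve:
    """Sliding-bin tachometric curve.

    ``rpt_centers`` is a 1-ms grid; each bin covers
    ``[center − (bin_width−1)/2, center + (bin_width−1)/2]`` inclusive.
    ``p_correct`` is NaN on unoccupied bins.  ``norm_factor`` is the display
    normalization (the larger of the two peak raw counts); it has no effect
    on ``p_correct``.
    """

    rpt_centers: np.ndarray
    n_correct: np.ndarray
    n_incorrect: np.ndarray
    f_c: np.ndarray
    f_i: np.ndarray
    p_correct: np.ndarray
    bin_width: float = 15.0
    step: float = 1.0
    norm_factor: float = 1.0

    @property
    def occupied(self) -> np.ndarray:
        return (self.n_correct + self.n_incorrect) > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rpt_center": self.rpt_centers,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "p_correct": self.p_correct,
        })


@dataclass(frozen=True)
class VFitParams:
    """Coefficients of the dual-sigmoid fit v(x); ``a_l`` is pinned at 0.5."""

    b: float
    a_r: float
    c_l: float
    c_r: float
    d_l: float
    d_r: float
    a_l: float = 0.5
    mae: float | None = None  # achieved mean absolute error, if fitted

    def __post_init__(self):
        if self.d_l <= 0 or self.d_r <= 0:
            raise ValueError("sigmoid widths d_l, d_r must be positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CurveFeatures:
    """Eight features of a fitted tachometric curve.

    ``left_edge`` and ``centerpoint`` are the midway crossings of the falling
    and rising branches (between chance and the minimum, and between the
    minimum and the asymptote, respectively); NaN when undefined (flat
    branch).  Slopes are per ms.
    """

    asymptote: float
    vortex_depth: float
    vortex_time: float
    slope_min: float
    slope_max: float
    left_edge: float
    centerpoint: float
    mean_perceptual_accuracy: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class FeatureCI:
    """Percentile-bootstrap confidence intervals for the curve features."""

    point: dict
    lower: dict
    upper: dict
    n_boot: int
    n_failed: int = 0
    warning: str | None = None


# ---------------------------------------------------------------------------

def compute_rpt(rt: float, gap: float):
    """Raw processing time: cue-viewing time ``rt − gap`` (a delay is a
    negative gap, so RT + delay is the same formula)."""
    return np.asarray(rt) - np.asarray(gap) if np.ndim(rt) or np.ndim(gap) else rt - gap


def compute_tachometric(trials: pd.DataFrame, bin_width: float = 15.0,
                        step: float = 1.0) -> TachCurve:
    """Compute the sliding-bin tachometric curve of a trial table.

    ``trials`` needs columns ``rpt_ms`` and ``correct``; rows with NaN rpt
    (e.g. unresponsive trials) are dropped.
    """
    if len(trials) == 0:
        raise ValueError("cannot compute a tachometric curve from an empty table")
    rpt = np.asarray(trials["rpt_ms"], dtype=float)
    correct = np.asarray(trials["correct"], dtype=bool)
    ok = np.isfinite(rpt)
    rpt, correct = rpt[ok], correct[ok]
    if rpt.size == 0:
        raise ValueError("no trials with finite rPT")
    half = (bin_width - 1.0) / 2.0
    lo_c = float(np.floor(rpt.min()))
    hi_c = float(np.ceil(rpt.max()))
    centers = np.arange(lo_c, hi_c + step, step)

    order = np.argsort(rpt, kind="stable")
    r_sorted = rpt[order]
    c_sorted = correct[order].astype(np.int64)
    cum_correct = np.concatenate([[0], np.cumsum(c_sorted)])
    lo = np.searchsorted(r_sorted, centers - half, side="left")
    hi = np.searchsorted(r_sorted, centers + half, side="right")
    n_tot = hi - lo
    n_correct = cum_correct[hi] - cum_correct[lo]
    n_incorrect = n_tot - n_correct

    norm = float(max(n_correct.max(), n_incorrect.max(), 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_tot > 0, n_correct / np.maximum(n_tot, 1), np.nan)
    return TachCurve(
        rpt_centers=centers,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        f_c=n_correct / norm,
        f_i=n_incorrect / norm,
        p_correct=p,
        bin_width=bin_width,
        step=step,
        norm_factor=norm,
    )


def evaluate_v(params: VFitParams, x):
    """Evaluate the fitted curve v(x) = max(s_L(x), s_R(x), 0)."""
    x = np.asarray(x, dtype=float)
    s_l = params.b + (params.a_l - params.b) * expit(-(x - params.c_l) / params.d_l)
    s_r = params.b + (params.a_r - params.b) * expit((x - params.c_r) / params.d_r)
    return np.maximum(np.maximum(s_l, s_r), 0.0)


def _mae(theta: np.ndarray, x: np.ndarray, p: np.ndarray,
         w: np.ndarray | None = None) -> float:
    b, a_r, c_l, c_r, d_l, d_r = theta
    if d_l <= 0.0 or d_r <= 0.0 or not (0.0 <= b <= 1.0) or not (0.0 <= a_r <= 1.0):
        return 1e6 + abs(d_l) + abs(d_r) + abs(b) + abs(a_r)
    s_l = b + (0.5 - b) * expit(-(x - c_l) / d_l)
    s_r = b + (a_r - b) * expit((x - c_r) / d_r)
    v = np.maximum(np.maximum(s_l, s_r), 0.0)
    err = np.abs(p - v)
    if w is None:
        return float(np.mean(err))
    return float(np.average(err, weights=w))


def _heuristic_start(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    i_min = int(np.argmin(p))
    b0 = max(float(p[i_min]), 0.0)
    right = p[x >= x[-1] - 50] if x.size > 50 else p
    a_r0 = float(np.clip(right.mean(), 0.6, 1.0))
    c_l0 = float(x[i_min] - 10)
    rise = np.flatnonzero((x > x[i_min]) & (p >= (b0 + a_r0) / 2))
    c_r0 = float(x[rise[0]]) if rise.size else float(x[i_min] + 30)
    return np.array([b0, a_r0, c_l0, c_r0, 5.0, 8.0])


def fit_tachometric(curve: TachCurve, n_starts: int = 20,
                    seed: int | np.random.Generator = 0,
                    init: VFitParams | None = None,
                    min_occupied: int = 20,
                    fit_range: tuple[float, float] | None = (-100.0, 400.0),
                    weighting: str = "counts",
                    maxfev: int = 4000) -> VFitParams:
    """Fit v(x) to the occupied bins of a tachometric curve.

    Minimizes the mean absolute error between ``p_correct`` and v at the bin
    centers via multi-start Nelder–Mead simplex search; A_L is pinned at 0.5.
    An explicit ``init`` adds a warm start (useful for bootstrap replicates,
    with a reduced ``n_starts``).  ``fit_range`` restricts the objective to
    bins within a fixed rPT window — the default [−100, 400] ms covers the
    behaviorally meaningful range while excluding sparse extreme-rPT bins;
    pass ``None`` to use every occupied bin.

    ``weighting="counts"`` (default) weights each bin's absolute error by
    its trial count, so the objective reflects the binomial precision of
    the bins; sparsely occupied bins at the rPT extremes otherwise inject
    enough noise to make the selected optimum unstable across datasets.
    ``weighting=None`` gives the unweighted mean.
    """
    occ = curve.occupied
    if fit_range is not None:
        occ = occ & (curve.rpt_centers >= fit_range[0]) & (curve.rpt_centers <= fit_range[1])
    x = np.asarray(curve.rpt_centers, dtype=float)[occ]
    p = np.asarray(curve.p_correct, dtype=float)[occ]
    if weighting == "counts":
        w = (curve.n_correct + curve.n_incorrect)[occ].astype(float)
    elif weighting is None:
        w = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if x.size < min_occupied:
        raise ValueError(
            f"need at least {min_occupied} occupied bins to fit, got {x.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base = _heuristic_start(x, p)
    starts = []
    if init is not None:
        starts.append(np.array([init.b, init.a_r, init.c_l, init.c_r,
                                init.d_l, init.d_r]))
    starts.append(base)
    # data-anchored variants with different branch steepnesses: the simplex
    # is sensitive to its starting widths on this multimodal surface
    for d_l0, d_r0 in ((2.0, 5.0), (2.0, 10.0), (5.0, 15.0), (10.0, 8.0)):
        v = base.copy()
        v[4], v[5] = d_l0, d_r0
        starts.append(v)
    lo_x, hi_x = float(x.min()), float(x.max())
    while len(starts) < n_starts:
        starts.append(np.array([
            rng.uniform(0.0, 0.5),
            rng.uniform(0.7, 1.0),
            rng.uniform(lo_x, hi_x),
            rng.uniform(lo_x, hi_x),
            rng.uniform(2.0, 40.0),
            rng.uniform(2.0, 40.0),
        ]))
    starts = starts[:max(n_starts, 1)]

    opts = {"fatol": 1e-6, "xatol": 1e-4, "maxiter": maxfev, "maxfev": maxfev}
    best = None
    for theta0 in starts:
        res = minimize(_mae, theta0, args=(x, p, w), method="Nelder-Mead",
                       options=opts)
        if best is None or res.fun < best.fun:
            best = res
    # polish restarts: re-running the simplex from the incumbent escapes
    # collapsed simplices (skipped for warm-started single-start refits)
    n_polish = 3 if n_starts >= 6 else (0 if init is not None else 1)
    for _ in range(n_polish):
        if best is None or not np.isfinite(best.fun):
            break
        res = minimize(_mae, best.x, args=(x, p, w), method="Nelder-Mead",
                       options=opts)
        if res.fun < best.fun - 1e-9:
            best = res
        else:
            break
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e6:
        partial = None
        if best is not None and np.isfinite(best.fun):
            b, a_r, c_l, c_r, d_l, d_r = best.x
            partial = VFitParams(b=b, a_r=a_r, c_l=c_l, c_r=c_r,
                                 d_l=max(d_l, 1e-6), d_r=max(d_r, 1e-6),
                                 mae=float(best.fun))
        raise FitNonConvergence("no start produced a valid fit", best=partial)
    b, a_r, c_l, c_r, d_l, d_r = best.x
    return VFitParams(b=float(b), a_r=float(a_r), c_l=float(c_l),
                      c_r=float(c_r), d_l=float(d_l), d_r=float(d_r),
                      mae=float(best.fun))


def extract_features(params: VFitParams,
                     rpt_range: tuple[float, float] = (-100.0, 400.0)) -> CurveFeatures:
    """Compute the eight curve features on a 1-ms evaluation grid.

    ``rpt_range`` should cover [0, 250] so the mean perceptual accuracy (the
    grid average of v over that window) is well defined.
    """
    lo, hi = rpt_range
    if lo > 0 or hi < 250:
        raise ValueError("rpt_range must cover [0, 250] ms")
    grid = np.arange(float(lo), float(hi) + 1.0)
    v = evaluate_v(params, grid)

    i_min = int(np.argmin(v))
    depth = float(v[i_min])
    v_time = float(grid[i_min])
    dv = np.gradient(v, grid)
    slope_min = float(dv.min())
    slope_max = float(dv.max())

    mid_l = (0.5 + depth) / 2.0
    left = np.flatnonzero((grid < grid[i_min]) & (v >= mid_l))
    left_edge = float(grid[left[-1]]) if left.size else float("nan")

    mid_r = (depth + params.a_r) / 2.0
    right = np.flatnonzero((grid > grid[i_min]) & (v >= mid_r))
    centerpoint = float(grid[right[0]]) if right.size else float("nan")

    pa_mask = (grid >= 0) & (grid <= 250)
    mpa = float(v[pa_mask].mean())
    return CurveFeatures(
        asymptote=float(params.a_r),
        vortex_depth=depth,
        vortex_time=v_time,
        slope_min=slope_min,
        slope_max=slope_max,
        left_edge=left_edge,
        centerpoint=centerpoint,
        mean_perceptual_accuracy=mpa,
    )


def rise_span(params: VFitParams, level_lo: float, level_hi: float,
              rpt_range: tuple[float, float] = (-100.0, 400.0)) -> float:
    """rPT distance between two level crossings on the ascending branch,
    measured on a 1-ms grid (NaN if either level is never reached)."""
    grid = np.arange(float(rpt_range[0]), float(rpt_range[1]) + 1.0)
    v = evaluate_v(params, grid)
    i_min = int(np.argmin(v))
    rising = np.flatnonzero(grid > grid[i_min])
    t = {}
    for lev in (level_lo, level_hi):
        idx = rising[v[rising] >= lev]
        if idx.size == 0:
            return float("nan")
        t[lev] = float(grid[idx[0]])
    return t[level_hi] - t[level_lo]


def bootstrap_features(trials: pd.DataFrame, n_boot: int = 10000,
                       seed: int | np.random.Generator = 0,
                       bin_width: float = 15.0,
                       n_starts_point: int = 20,
                       n_starts_boot: int = 3,
                       rpt_range: tuple[float, float] | None = None) -> FeatureCI:
    """Percentile-bootstrap CIs for the eight curve features.

    Resamples trials with replacement (same n), recomputes the curve, refits
    v (warm-started at the point fit), and re-extracts the features; the CI
    is the 2.5–97.5 percentile band.  Replicates whose fit fails are dropped
    and counted; more than 5% failures attaches a warning.
    """
    if len(trials) < 100:
        raise ValueError("need at least 100 trials to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = trials.loc[np.isfinite(np.asarray(trials["rpt_ms"], dtype=float))]
    rpt = np.asarray(sub["rpt_ms"], dtype=float)
    correct = np.asarray(sub["correct"], dtype=bool)
    n = rpt.size

    curve = compute_tachometric(sub, bin_width=bin_width)
    point_fit = fit_tachometric(curve, n_starts=n_starts_point, seed=rng)
    if rpt_range is None:
        lo = min(float(np.floor(rpt.min())), 0.0)
        hi = max(float(np.ceil(rpt.max())), 250.0)
        rpt_range = (lo, hi)
    point = extract_features(point_fit, rpt_range).to_dict()

    draws: dict[str, list] = {k: [] for k in FEATURE_NAMES}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = pd.DataFrame({"rpt_ms": rpt[idx], "correct": correct[idx]})
        try:
            c = compute_tachometric(rep, bin_width=bin_width)
            f = fit_tachometric(c, n_starts=n_starts_boot, seed=rng,
                                init=point_fit, maxfev=1500)
            feats = extract_features(f, rpt_range).to_dict()
        except (ValueError, FitNonConvergence):
            n_failed += 1
            continue
        for k in FEATURE_NAMES:
            draws[k].append(feats[k])

    warning = None
    if n_failed > 0.05 * n_boot:
        warning = f"{n_failed}/{n_boot} bootstrap replicates failed to fit"
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    lower = {}
    upper = {}
    for k in FEATURE_NAMES:
        arr = np.asarray(draws[k], dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            lower[k] = upper[k] = float("nan")
        else:
            lower[k] = float(np.percentile(arr, 2.5))
            upper[k] = float(np.percentile(arr, 97.5))
    return FeatureCI(point=point, lower=lower, upper=upper,
                     n_boot=n_boot, n_failed=n_failed, warning=warning)
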