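"""Individual-differences analyses: associations between per-participant
summary measures while controlling for cue luminance.

With three luminance conditions per participant, any two performance
measures that both improve with luminance will appear correlated; the
partial correlation (Pearson on residuals, or Spearman on rank residuals)
removes the association carried by luminance alone.  An ordinary linear
model with luminance as a covariate provides an equivalent third check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .race_model import RT_DEADLINE_MS
from .tachometrics import compute_tachometric, fit_tachometric, extract_features

__all__ = [
    "partial_correlation",
    "regression_with_covariate",
    "participant_summaries",
    "LUMINANCE_ORDINAL",
    "LUMINANCE_CD_M2",
]

#: default ordinal coding of the luminance covariate
LUMINANCE_ORDINAL = {"high": 1.0, "medium": 2.0, "low": 3.0}
#: measured luminances (cd/m^2), for the optional log-luminance coding
LUMINANCE_CD_M2 = {"high": 17.6, "medium": 0.35, "low": 0.22}


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least-squares residuals of v after removing an intercept and z."""
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, z, method: str = "spearman") -> tuple[float, float]:
    """Partial correlation of x and y controlling for covariate z.

    Pearson: correlate the residuals of x and y after linearly removing z.
    Spearman: the same computation on rank-transformed data.  The two-sided
    p-value uses the t approximation with n − 3 degrees of freedom.

    Returns
    -------
    (rho, p_value)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a partial correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if method == "spearman":
        x, y, z = (stats.rankdata(v) for v in (x, y, z))
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    sx = float(np.sqrt(np.sum(rx * rx)))
    sy = float(np.sqrt(np.sum(ry * ry)))
    tol_x = 1e-10 * (float(np.linalg.norm(x)) + 1.0)
    tol_y = 1e-10 * (float(np.linalg.norm(y)) + 1.0)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero variance after residualization; partial correlation undefined")
    rho = float(np.dot(rx, ry) / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    dof = n - 3
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return rho, max(p, np.finfo(float).tiny)


def regression_with_covariate(x, y, z) -> pd.DataFrame:
    """OLS of y on (x, z, intercept); returns the full coefficient table.

    The row ``x`` carries the association of interest; its t-test is
    algebraically equivalent to the partial Pearson correlation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    design = pd.DataFrame({"const": 1.0, "x": x, "z": z})
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = design[["x", "z"]].corr().abs()
        raise ValueError(
            "rank-deficient design matrix; check collinearity between 'x' and 'z' "
            f"(|corr| = {corr.loc['x', 'z']:.3f}) or constant columns")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame({
        "coef": fit.params,
        "stderr": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })


def participant_summaries(trials: pd.DataFrame,
                          n_fit_starts: int = 20,
                          seed: int | np.random.Generator = 0,
                          include_deadline: bool = True) -> pd.DataFrame:
    """Per participant × luminance summary table for association analyses.

    For each cell: mean observed accuracy (proportion correct over urgent
    trials), mean RT over correct and incorrect trials, and the perceptual
    features of the fitted tachometric curve (mean perceptual accuracy and
    centerpoint).  Unresponsive trials are excluded; trials beyond the RT
    deadline are kept unless ``include_deadline`` is False.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = trials[(trials["gap_ms"] >= 0) & (trials["outcome_class"] != "no_response")]
    if not include_deadline:
        d = d[d["rt_ms"] <= RT_DEADLINE_MS]
    rows = []
    for (pid, lum), cell in d.groupby(["participant", "luminance"], sort=False):
        curve = compute_tachometric(cell)
        fit = fit_tachometric(curve, n_starts=n_fit_starts, seed=rng)
        feats = extract_features(fit)
        rows.append({
            "participant": pid,
            "luminance": lum,
            "n_trials": len(cell),
            "mean_observed_accuracy": float(cell["correct"].mean()),
            "mean_rt": float(cell["rt_ms"].mean()),
            "mean_perceptual_accuracy": feats.mean_perceptual_accuracy,
            "centerpoint": feats.centerpoint,
            "vortex_time": feats.vortex_time,
            "asymptote": feats.asymptote,
        })
    return pd.DataFrame(rows)
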