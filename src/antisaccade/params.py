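"""Parameter containers for the accelerated race-to-threshold model.

The model describes a single urgent antisaccade trial as a race between two
oculomotor plans — one toward the cue and one toward the diametrically
opposite (anti) location — rising toward a fixed trigger threshold.  One
:class:`LuminanceParams` row holds the 15 model parameters for one cue
luminance condition; :class:`SimConstants` holds the fixed quantities of the
simulation (threshold, delays, time step) that are never fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum

__all__ = [
    "LuminanceParams",
    "SimConstants",
    "ModelVariant",
    "POOLED_PARAMS",
    "LUMINANCE_LEVELS",
]


class ModelVariant(str, Enum):
    """Which exogenous mechanisms operate during the ERI.

    ``FULL`` applies both: the anti plan halts (or is suppressed) and the cue
    plan halts briefly then accelerates.  ``ACCEL_ONLY`` leaves the anti plan
    unperturbed; ``HALT_ONLY`` leaves the cue plan unperturbed (no exogenous
    acceleration).  The restricted variants isolate the behavioral signature
    of each mechanism.
    """

    FULL = "full"
    ACCEL_ONLY = "accel_only"
    HALT_ONLY = "halt_only"


@dataclass(frozen=True)
class LuminanceParams:
    """The 15 race-model parameters for one luminance condition.

    Units: build-up rates in AU/ms, times in ms, accelerations in AU/ms^2.

    Parameters
    ----------
    mu_b, sigma_b, rho_b
        Mean, SD and correlation of the two initial build-up rates, drawn
        jointly from a bivariate Gaussian at trial start.
    mu_go_aff, sigma_go_aff
        Gaussian afferent delay of the go signal (sub-floor draws rejected).
    mu_cue_aff, sigma_cue_aff
        Gaussian afferent delay of cue detection (sub-floor draws rejected).
    mu_eri, sigma_eri
        Gaussian duration of the exogenous response interval (ERI); negative
        draws are reset to zero.
    g_eri
        Gain applied to both initial build-up rates while a plan is halted
        during the ERI; zero halts the plan, negative values suppress it.
    delta_eri
        Initial portion of the ERI during which the cue plan halts before the
        exogenous acceleration kicks in.
    a_ex
        Exogenous acceleration of the cue plan during the remainder of the ERI.
    d_end
        Endogenous deceleration (negative) of the cue plan after the ERI.
    a_end
        Endogenous acceleration of the anti plan after the ERI.
    lapse
        Probability that the endogenous update never arrives (epoch 3 keeps
        the ERI-final build-up rates).
    """

    mu_b: float
    sigma_b: float
    rho_b: float
    mu_go_aff: float
    sigma_go_aff: float
    mu_cue_aff: float
    sigma_cue_aff: float
    mu_eri: float
    sigma_eri: float
    g_eri: float
    delta_eri: float
    a_ex: float
    d_end: float
    a_end: float
    lapse: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
        if self.sigma_b < 0 or self.sigma_go_aff < 0 or self.sigma_cue_aff < 0 or self.sigma_eri < 0:
            raise ValueError("standard deviations must be nonnegative")
        if abs(self.rho_b) > 1:
            raise ValueError(f"rho_b must lie in [-1, 1], got {self.rho_b}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse probability must lie in [0, 1], got {self.lapse}")
        if self.g_eri > 0:
            raise ValueError(f"g_eri must be <= 0, got {self.g_eri}")
        if self.d_end > 0:
            raise ValueError(f"d_end must be <= 0, got {self.d_end}")
        if self.a_end < 0:
            raise ValueError(f"a_end must be >= 0, got {self.a_end}")
        if self.delta_eri < 0:
            raise ValueError(f"delta_eri must be >= 0, got {self.delta_eri}")

    def replace(self, **kwargs) -> "LuminanceParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "LuminanceParams":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class SimConstants:
    """Fixed simulation constants (never fitted).

    ``threshold`` is the saccade trigger level (1000 AU); ``efferent_delay``
    the time from threshold crossing to saccade onset (20 ms);
    ``afferent_floor`` the minimum afferent delay (20 ms; smaller Gaussian
    draws are rejected); ``dt`` the integration step (1 ms); ``t_max`` a hard
    cap after which a trial is flagged unresponsive.
    """

    threshold: float = 1000.0
    efferent_delay: float = 20.0
    dt: float = 1.0
    afferent_floor: float = 20.0
    t_max: float = 5000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{f.name} must be finite and positive, got {v!r}")


LUMINANCE_LEVELS = ("high", "medium", "low")

#: Pooled-data parameter sets for the three cue luminance conditions.  The
#: motor block (mu_b .. sigma_go_aff) is shared across conditions because all
#: trials are identical up to cue presentation.
POOLED_PARAMS: dict[str, LuminanceParams] = {
    "high": LuminanceParams(
        mu_b=1.4, sigma_b=3.74, rho_b=-0.95,
        mu_go_aff=51.0, sigma_go_aff=36.0,
        mu_cue_aff=76.0, sigma_cue_aff=5.0,
        mu_eri=24.0, sigma_eri=4.0,
        g_eri=0.0, delta_eri=10.0,
        a_ex=0.96, d_end=-0.7, a_end=0.17, lapse=0.02,
    ),
    "medium": LuminanceParams(
        mu_b=1.4, sigma_b=3.74, rho_b=-0.95,
        mu_go_aff=51.0, sigma_go_aff=36.0,
        mu_cue_aff=104.0, sigma_cue_aff=13.0,
        mu_eri=24.0, sigma_eri=3.0,
        g_eri=0.0, delta_eri=14.0,
        a_ex=1.15, d_end=-0.54, a_end=0.17, lapse=0.02,
    ),
    "low": LuminanceParams(
        mu_b=1.4, sigma_b=3.74, rho_b=-0.95,
        mu_go_aff=51.0, sigma_go_aff=36.0,
        mu_cue_aff=126.0, sigma_cue_aff=19.0,
        mu_eri=24.0, sigma_eri=10.0,
        g_eri=0.0, delta_eri=14.0,
        a_ex=0.58, d_end=-0.29, a_end=0.14, lapse=0.1,
    ),
}
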