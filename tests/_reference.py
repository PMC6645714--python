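"""Independent reference implementations used as test oracles.

``reference_trial`` is a deliberately plain, scalar, step-by-step
transcription of the three-epoch race recurrences (state machine over
build-up rates), written independently of the vectorized engine.  Within
each step the build-up rates are updated first, then integrated, then the
zero floor and threshold are applied — the same convention the engine
documents.  Event times must lie on the step grid for exact agreement.

``linear_crossing_time`` is the closed-form crossing time for a purely
linear race (no cue influence before crossing).
"""

from __future__ import annotations

import math


def linear_crossing_time(b: float, t_on: float, threshold: float,
                         dt: float = 1.0) -> float:
    """First grid time with b * (t - t_on) >= threshold (b > 0)."""
    if b <= 0:
        return math.inf
    return t_on + math.ceil(threshold / (b * dt)) * dt


def reference_trial(*, b_c0: float, b_a0: float, t_on: float, gap: float,
                    cue_delay: float, eri_dur: float, lapse: bool,
                    g_eri: float, delta_eri: float, a_ex: float,
                    d_end: float, a_end: float,
                    threshold: float = 1000.0, efferent_delay: float = 20.0,
                    dt: float = 1.0, t_max: float = 5000.0,
                    variant: str = "full"):
    """Simulate one trial; returns (rt, winner) with winner in
    {"cue", "anti", None} and rt = crossing time + efferent delay (None if
    no crossing by t_max).  Ties report winner "tie"."""
    cue_perturbed = variant != "halt_only"
    anti_halted = variant != "accel_only"

    eri_start = gap + cue_delay
    eri_end = eri_start + eri_dur
    accel_start = eri_start + min(delta_eri, eri_dur)

    r_c = r_a = 0.0
    b_c = b_a = 0.0
    t = 0.0
    n_steps = int(round(t_max / dt))
    for _ in range(n_steps):
        t += dt
        # ---- rate updates (state machine over epochs) ----
        if t <= t_on:
            b_c = 0.0
            b_a = 0.0
        else:
            # cue plan
            if t <= eri_start:
                b_c = b_c0
            elif t <= eri_end and cue_perturbed:
                if t <= accel_start:
                    b_c = g_eri * b_c0
                else:
                    # recovered at accel_start, gains a_ex each step since
                    b_c = b_c0 + a_ex * (t - accel_start)
            elif t <= eri_end:
                b_c = b_c0
            else:
                b_c_final = (b_c0 + a_ex * max(eri_dur - delta_eri, 0.0)
                             if cue_perturbed else b_c0)
                b_c = b_c_final if lapse else b_c_final + d_end * (t - eri_end)
            # anti plan
            if t <= eri_start:
                b_a = b_a0
            elif t <= eri_end:
                b_a = g_eri * b_a0 if anti_halted else b_a0
            else:
                b_a = b_a0 if lapse else b_a0 + a_end * (t - eri_end)
        # ---- integrate, floor, threshold ----
        r_c = max(r_c + b_c * dt, 0.0)
        r_a = max(r_a + b_a * dt, 0.0)
        c_hit = r_c >= threshold
        a_hit = r_a >= threshold
        if c_hit or a_hit:
            if c_hit and a_hit:
                if r_a > r_c:
                    winner = "anti"
                elif r_c > r_a:
                    winner = "cue"
                else:
                    winner = "tie"
            else:
                winner = "anti" if a_hit else "cue"
            return t + efferent_delay, winner
    return None, None
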