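"""Tachometric-curve estimation, v(x) fitting, features and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from antisaccade.tachometrics import (
    FEATURE_NAMES,
    TachCurve,
    VFitParams,
    bootstrap_features,
    compute_rpt,
    compute_tachometric,
    evaluate_v,
    extract_features,
    fit_tachometric,
    rise_span,
)


def brute_force_curve(rpts, correct, bin_width=15, step=1):
    """Exhaustive per-center counting oracle."""
    rpts = np.asarray(rpts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    half = (bin_width - 1) / 2
    centers = np.arange(np.floor(rpts.min()), np.ceil(rpts.max()) + step, step)
    rows = []
    for c in centers:
        in_bin = (rpts >= c - half) & (rpts <= c + half)
        nc = int((in_bin & correct).sum())
        ni = int((in_bin & ~correct).sum())
        rows.append((c, nc, ni, nc / (nc + ni) if nc + ni else np.nan))
    return rows


def curve_from_params(params, centers, n_per_bin=1000):
    """Noiseless TachCurve whose p_correct equals v at the centers."""
    v = evaluate_v(params, centers)
    nc = np.round(v * n_per_bin).astype(int)
    return TachCurve(rpt_centers=np.asarray(centers, float), n_correct=nc,
                     n_incorrect=n_per_bin - nc, f_c=nc / n_per_bin,
                     f_i=1 - nc / n_per_bin, p_correct=nc / n_per_bin)


class TestComputeRpt:
    @pytest.mark.parametrize("rt,gap,expected", [
        (369.0, 150.0, 219.0),   # informed choice
        (206.0, 150.0, 56.0),    # correct guess
        (300.0, 0.0, 300.0),
        (250.0, -100.0, 350.0),  # delay trial: rPT = RT + delay
    ])
    def test_rpt_is_rt_minus_gap(self, rt, gap, expected):
        assert compute_rpt(rt, gap) == expected


class TestComputeTachometric:
    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            compute_tachometric(pd.DataFrame({"rpt_ms": [], "correct": []}))

    def test_all_correct_gives_unit_proportion(self):
        df = pd.DataFrame({"rpt_ms": np.arange(100, 160, 2.0), "correct": True})
        c = compute_tachometric(df)
        assert np.all(c.p_correct[c.occupied] == 1.0)

    def test_balanced_bin_gives_half(self):
        df = pd.DataFrame({"rpt_ms": [100.0] * 10, "correct": [True, False] * 5})
        c = compute_tachometric(df)
        assert np.all(c.p_correct[c.occupied] == 0.5)

    def test_matches_brute_force_on_hand_data(self):
        rpts = [100, 100, 105, 110, 150, 150, 155, 160]
        corr = [0, 0, 0, 1, 1, 1, 1, 0]
        c = compute_tachometric(pd.DataFrame({"rpt_ms": rpts, "correct": corr}))
        for center, nc, ni, p in brute_force_curve(rpts, corr):
            i = int(center - c.rpt_centers[0])
            assert c.n_correct[i] == nc and c.n_incorrect[i] == ni
            if nc + ni:
                assert c.p_correct[i] == p
            else:
                assert np.isnan(c.p_correct[i])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(-50, 300), st.booleans()),
                    min_size=1, max_size=60))
    def test_matches_brute_force_on_random_data(self, trials):
        rpts = [t[0] for t in trials]
        corr = [t[1] for t in trials]
        c = compute_tachometric(pd.DataFrame({"rpt_ms": rpts, "correct": corr}))
        for center, nc, ni, p in brute_force_curve(rpts, corr):
            i = int(center - c.rpt_centers[0])
            assert c.n_correct[i] == nc and c.n_incorrect[i] == ni

    def test_proportion_invariant_to_normalization(self, high_lum_trials):
        c = compute_tachometric(high_lum_trials)
        occ = c.occupied
        # p equals the count ratio regardless of the display normalization
        ratio = c.n_correct[occ] / (c.n_correct[occ] + c.n_incorrect[occ])
        np.testing.assert_allclose(c.p_correct[occ], ratio)
        np.testing.assert_allclose(c.f_c, c.n_correct / c.norm_factor)


class TestEvaluateV:
    def test_sigmoid_limits_and_midpoint(self):
        p = VFitParams(b=0.05, a_r=0.95, c_l=100, c_r=140, d_l=4, d_r=6)
        assert evaluate_v(p, -1e5) == pytest.approx(0.5)
        assert evaluate_v(p, 1e5) == pytest.approx(0.95)
        # midpoint identity of the rising sigmoid, where s_L is negligible
        s_r_mid = p.b + (p.a_r - p.b) / 2
        assert evaluate_v(p, p.c_r) == pytest.approx(s_r_mid, abs=1e-6)

    def test_never_negative_even_with_negative_b(self):
        p = VFitParams(b=-0.2, a_r=0.9, c_l=50, c_r=150, d_l=5, d_r=5)
        x = np.arange(-100, 400.0)
        assert np.all(evaluate_v(p, x) >= 0.0)

    def test_nonpositive_widths_rejected(self):
        with pytest.raises(ValueError):
            VFitParams(b=0.1, a_r=0.9, c_l=50, c_r=150, d_l=0.0, d_r=5)

    @settings(max_examples=50, deadline=None)
    @given(b=st.floats(0, 1), a_r=st.floats(0, 1),
           c_l=st.floats(0, 200), c_r=st.floats(0, 200),
           d_l=st.floats(0.5, 40), d_r=st.floats(0.5, 40),
           x=st.floats(-500, 500))
    def test_bounded_when_coefficients_are_proportions(self, b, a_r, c_l, c_r,
                                                       d_l, d_r, x):
        p = VFitParams(b=b, a_r=a_r, c_l=c_l, c_r=c_r, d_l=d_l, d_r=d_r)
        v = float(evaluate_v(p, x))
        assert 0.0 <= v <= max(0.5, a_r, b) + 1e-12


class TestFitTachometric:
    TRUE = VFitParams(b=0.05, a_r=0.98, c_l=95, c_r=140, d_l=4, d_r=6)

    def test_recovers_noiseless_curve(self):
        centers = np.arange(-50.0, 351.0)
        curve = curve_from_params(self.TRUE, centers, n_per_bin=10**6)
        fit = fit_tachometric(curve, seed=0)
        assert fit.mae < 1e-4
        f_fit = extract_features(fit, (-50, 350))
        f_true = extract_features(self.TRUE, (-50, 350))
        for k in FEATURE_NAMES:
            assert getattr(f_fit, k) == pytest.approx(getattr(f_true, k),
                                                      abs=1.5e-2)

    def test_left_asymptote_pinned_at_half(self, high_lum_trials):
        fit = fit_tachometric(compute_tachometric(high_lum_trials), seed=1)
        assert fit.a_l == 0.5

    def test_requires_enough_occupied_bins(self):
        df = pd.DataFrame({"rpt_ms": [100.0] * 5, "correct": [True] * 5})
        with pytest.raises(ValueError):
            fit_tachometric(compute_tachometric(df))

    def test_noisy_fit_error_at_binomial_scale(self, rng):
        centers = np.arange(-50.0, 351.0)
        v = evaluate_v(self.TRUE, centers)
        n = 200
        nc = rng.binomial(n, v)
        curve = TachCurve(rpt_centers=centers, n_correct=nc, n_incorrect=n - nc,
                          f_c=nc / n, f_i=1 - nc / n, p_correct=nc / n)
        fit = fit_tachometric(curve, seed=2)
        binom_sd = np.mean(np.sqrt(v * (1 - v) / n))
        assert fit.mae <= 2 * binom_sd
        # independent coarse grid-search oracle cannot beat the simplex much
        grid_best = np.inf
        for b in (0.0, 0.05, 0.1):
            for c_l in (85.0, 95.0, 105.0):
                for c_r in (130.0, 140.0, 150.0):
                    for d_l in (2.0, 4.0, 8.0):
                        for d_r in (4.0, 6.0, 10.0):
                            cand = VFitParams(b=b, a_r=0.98, c_l=c_l, c_r=c_r,
                                              d_l=d_l, d_r=d_r)
                            err = np.mean(np.abs(curve.p_correct
                                                 - evaluate_v(cand, centers)))
                            grid_best = min(grid_best, err)
        assert fit.mae <= grid_best + 5e-4

    def test_fit_idempotent_on_its_own_curve(self, high_lum_trials):
        fit1 = fit_tachometric(compute_tachometric(high_lum_trials), seed=3)
        centers = np.arange(-100.0, 401.0)
        refit = fit_tachometric(curve_from_params(fit1, centers, 10**6),
                                seed=4, init=fit1)
        f1 = extract_features(fit1)
        f2 = extract_features(refit)
        for k in ("vortex_depth", "mean_perceptual_accuracy", "asymptote"):
            assert getattr(f1, k) == pytest.approx(getattr(f2, k), abs=1e-3)
        for k in ("vortex_time", "left_edge", "centerpoint"):
            assert getattr(f1, k) == pytest.approx(getattr(f2, k), abs=1.0)


class TestExtractFeatures:
    def test_constant_chance_curve(self):
        p = VFitParams(b=0.5, a_r=0.5, c_l=100, c_r=150, d_l=5, d_r=5)
        f = extract_features(p)
        assert f.mean_perceptual_accuracy == pytest.approx(0.5)
        assert f.vortex_depth == pytest.approx(0.5)
        assert f.slope_max == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_grid_oracle(self):
        p = VFitParams(b=0.05, a_r=0.98, c_l=95, c_r=140, d_l=4, d_r=6)
        f = extract_features(p, (-100, 400))
        # independent dense evaluation at 0.01-ms resolution
        x = np.arange(-100, 400, 0.01)
        s_l = p.b + (0.5 - p.b) * expit(-(x - p.c_l) / p.d_l)
        s_r = p.b + (p.a_r - p.b) * expit((x - p.c_r) / p.d_r)
        v = np.maximum(np.maximum(s_l, s_r), 0.0)
        i = np.argmin(v)
        # the 1-ms evaluation grid quantizes the flat valley slightly
        assert f.vortex_depth == pytest.approx(v[i], abs=1e-3)
        assert f.vortex_time == pytest.approx(x[i], abs=1.0)
        dv = np.diff(v) / 0.01
        assert f.slope_min == pytest.approx(dv.min(), abs=1e-3)
        assert f.slope_max == pytest.approx(dv.max(), abs=1e-3)
        mid_l = (0.5 + v[i]) / 2
        left = x[(x < x[i]) & (v >= mid_l)]
        assert f.left_edge == pytest.approx(left[-1], abs=1.0)
        mid_r = (v[i] + p.a_r) / 2
        right = x[(x > x[i]) & (v >= mid_r)]
        assert f.centerpoint == pytest.approx(right[0], abs=1.0)
        in_win = (x >= 0) & (x <= 250)
        assert f.mean_perceptual_accuracy == pytest.approx(v[in_win].mean(),
                                                           abs=1e-3)
        assert f.asymptote == p.a_r

    def test_feature_ordering(self, high_lum_trials):
        fit = fit_tachometric(compute_tachometric(high_lum_trials), seed=5)
        f = extract_features(fit)
        assert f.left_edge <= f.vortex_time <= f.centerpoint
        assert 0.0 <= f.vortex_depth <= f.asymptote

    def test_range_must_cover_accuracy_window(self):
        p = VFitParams(b=0.1, a_r=0.9, c_l=95, c_r=140, d_l=4, d_r=6)
        with pytest.raises(ValueError):
            extract_features(p, (0, 200))

    def test_rise_span_matches_analytic_sigmoid(self):
        # pure rising sigmoid: crossings known in closed form
        p = VFitParams(b=0.0, a_r=1.0, c_l=-1000, c_r=150, d_l=1, d_r=8)
        span = rise_span(p, 0.25, 0.75, (-100, 500))
        expected = 8 * 2 * np.log(3)  # x(0.75) - x(0.25) for logistic
        assert span == pytest.approx(expected, abs=1.5)


class TestBootstrapFeatures:
    def test_requires_minimum_trials(self):
        df = pd.DataFrame({"rpt_ms": np.arange(50.0), "correct": True})
        with pytest.raises(ValueError):
            bootstrap_features(df, n_boot=10, seed=0)

    def test_degenerate_data_gives_tight_depth_interval(self):
        # every bin all-correct or all-incorrect, large n: resampling cannot
        # change any bin proportion
        rpts = np.concatenate([np.full(800, 100.0), np.full(800, 200.0),
                               np.full(400, 60.0), np.full(400, 260.0)])
        corr = np.concatenate([np.zeros(800, bool), np.ones(800, bool),
                               np.ones(400, bool), np.ones(400, bool)])
        df = pd.DataFrame({"rpt_ms": rpts, "correct": corr})
        ci = bootstrap_features(df, n_boot=60, seed=0, n_starts_boot=2)
        width = ci.upper["vortex_depth"] - ci.lower["vortex_depth"]
        assert width < 0.02

    def test_intervals_contain_point_estimates(self, high_lum_trials):
        sub = high_lum_trials.sample(6000, random_state=0)
        ci = bootstrap_features(sub, n_boot=40, seed=1, n_starts_boot=2)
        contained = [ci.lower[k] - 1e-9 <= ci.point[k] <= ci.upper[k] + 1e-9
                     for k in FEATURE_NAMES
                     if np.isfinite(ci.point[k])]
        assert np.mean(contained) >= 0.75
        assert ci.n_failed <= 0.05 * 40
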