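"""Ocular metric unit and property tests with independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightload.ocular import (
    GazeSeries,
    angular_velocity,
    detect_fixations,
    fixation_stats,
    haar_mra,
    haar_dwt_coeffs,
    nni,
    normalize_pupil,
    pd_lowfreq_std,
    preprocess_pupil,
)

from conftest import make_gaze, random_gaze


# ---------------------------------------------------------------------------
# oracles


def brute_force_fixations(g, threshold=30.0):
    """Per-sample I-VT classification by explicit loop (independent oracle)."""
    idx = [i for i in range(len(g)) if g.valid[i]]
    events = []
    cur = None
    for a, b in zip(idx[:-1], idx[1:]):
        va, vb = g.dir[a], g.dir[b]
        ang = np.degrees(
            np.arctan2(np.linalg.norm(np.cross(va, vb)), np.dot(va, vb))
        )
        vel = ang / (g.t[b] - g.t[a])
        if vel < threshold:
            if cur is None:
                cur = [g.t[a], g.t[b]]
            else:
                cur[1] = g.t[b]
        else:
            if cur is not None:
                events.append(tuple(cur))
                cur = None
    if cur is not None:
        events.append(tuple(cur))
    return events


def natural_spline_oracle(tv, yv, t_query):
    """Natural cubic spline by direct tridiagonal solve (no scipy.interpolate)."""
    n = len(tv)
    h = np.diff(tv)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 3 * ((yv[i + 1] - yv[i]) / h[i] - (yv[i] - yv[i - 1]) / h[i - 1])
    c = np.linalg.solve(A, rhs)
    out = np.empty_like(t_query, dtype=float)
    for j, tq in enumerate(t_query):
        i = np.clip(np.searchsorted(tv, tq) - 1, 0, n - 2)
        dt = tq - tv[i]
        b = (yv[i + 1] - yv[i]) / h[i] - h[i] * (2 * c[i] + c[i + 1]) / 3
        d = (c[i + 1] - c[i]) / (3 * h[i])
        out[j] = yv[i] + b * dt + c[i] * dt**2 + d * dt**3
    return out


def block_mean_mra_oracle(x, levels):
    """Haar approximation/detail components by recursive block averaging."""
    comps = []
    prev = x.astype(float)
    for lev in range(1, levels + 1):
        size = 2**lev
        means = x.reshape(-1, size).mean(axis=1)
        approx = np.repeat(means, size)
        comps.append(prev - approx)  # detail component at this level
        prev = approx
    return prev, comps  # (approx at deepest level, details fine->coarse)


# ---------------------------------------------------------------------------
# pupil preprocessing


class TestPreprocessPupil:
    def test_all_valid_is_identity(self):
        t = np.arange(20) / 120.0
        pd = 3.0 + 0.01 * np.arange(20)
        g = make_gaze(t, np.zeros((20, 2)), pd_mm=pd)
        np.testing.assert_array_equal(preprocess_pupil(g, "left"), pd)

    def test_interior_gap_on_linear_trend_fills_collinearly(self):
        n = 60
        t = np.arange(n) / 120.0
        pd = np.linspace(3.0, 3.4, n)
        valid = np.ones(n, bool)
        valid[25:35] = False
        corrupted = pd.copy()
        corrupted[~valid] = 0.0
        g = make_gaze(t, np.zeros((n, 2)), valid=valid, pd_mm=corrupted)
        out = preprocess_pupil(g, "left")
        np.testing.assert_allclose(out, pd, atol=1e-9)

    def test_interior_gap_matches_tridiagonal_spline_oracle(self):
        rng = np.random.default_rng(3)
        n = 80
        t = np.arange(n) / 120.0
        pd = 3.5 + 0.2 * np.sin(2 * np.pi * 0.8 * t) + rng.normal(0, 0.01, n)
        valid = np.ones(n, bool)
        valid[40:50] = False
        g = make_gaze(t, np.zeros((n, 2)), valid=valid, pd_mm=pd)
        out = preprocess_pupil(g, "left")
        expected = natural_spline_oracle(t[valid], pd[valid], t[~valid])
        np.testing.assert_allclose(out[~valid], expected, atol=1e-9)

    def test_edge_gap_takes_nearest_valid_value(self):
        n = 40
        t = np.arange(n) / 120.0
        pd = np.linspace(3.0, 3.4, n)
        valid = np.ones(n, bool)
        valid[:5] = False
        valid[-4:] = False
        g = make_gaze(t, np.zeros((n, 2)), valid=valid, pd_mm=pd)
        out = preprocess_pupil(g, "left")
        assert np.all(out[:5] == pd[5])
        assert np.all(out[-4:] == pd[-5])

    def test_too_few_valid_samples_raises(self):
        n = 10
        valid = np.zeros(n, bool)
        valid[:3] = True
        g = make_gaze(np.arange(n) / 120.0, np.zeros((n, 2)), valid=valid)
        with pytest.raises(ValueError, match="valid"):
            preprocess_pupil(g, "left")


class TestNormalizePupil:
    def test_constant_series_gives_zero_percent(self):
        t = np.arange(0, 10, 1 / 120)
        out = normalize_pupil(t, np.full(t.size, 4.0))
        assert out.baseline == 4.0
        np.testing.assert_array_equal(out.pct_pd, 0.0)

    def test_five_percent_above_baseline(self):
        t = np.arange(0, 10, 1 / 120)
        pd = np.full(t.size, 4.0)
        pd[t > 6] = 4.2
        out = normalize_pupil(t, pd)
        np.testing.assert_allclose(out.pct_pd[t > 6], 5.0)

    def test_baseline_is_first_window_max_not_global(self):
        t = np.arange(0, 20, 1 / 120)
        pd = np.full(t.size, 3.2)
        pd[t <= 4] = 3.5
        pd[t > 10] = 3.9  # later, larger peak must not become the baseline
        out = normalize_pupil(t, pd)
        assert out.baseline == 3.5

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(0, 10, 1 / 120)
        with pytest.raises(ValueError, match="baseline"):
            normalize_pupil(t, np.full(t.size, -1.0))

    def test_short_series_rejected(self):
        t = np.arange(0, 3, 1 / 120)
        with pytest.raises(ValueError, match="baseline window"):
            normalize_pupil(t, np.full(t.size, 4.0))


# ---------------------------------------------------------------------------
# Haar multiresolution analysis


class TestHaarMRA:
    def test_constant_signal_is_pure_approximation(self):
        x = np.full(256, 3.7)
        m = haar_mra(x, levels=7)
        np.testing.assert_allclose(m.approx, 3.7, atol=1e-10)
        for d in m.details:
            np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_alternating_signal_lives_in_finest_detail(self):
        x = np.tile([1.0, -1.0], 64)
        m = haar_mra(x, levels=7)
        np.testing.assert_allclose(m.approx, 0.0, atol=1e-10)
        np.testing.assert_allclose(m.details[0], x, atol=1e-10)
        for d in m.details[1:]:
            np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_components_match_block_mean_oracle_on_dyadic_input(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=1024)
        m = haar_mra(x, levels=7)
        approx_oracle, details_oracle = block_mean_mra_oracle(x, 7)
        np.testing.assert_allclose(m.approx, approx_oracle, atol=1e-10)
        for ours, oracle in zip(m.details, details_oracle):
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_additive_reconstruction_any_length(self):
        rng = np.random.default_rng(12)
        for n in (128, 300, 1000):
            x = rng.normal(size=n)
            m = haar_mra(x, levels=7)
            np.testing.assert_allclose(m.reconstruct(), x, atol=1e-8)

    def test_coefficient_energy_conservation_dyadic(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=512)
        coeffs = haar_dwt_coeffs(x, levels=7)
        energy = sum(float((c**2).sum()) for c in coeffs)
        assert energy == pytest.approx(float((x**2).sum()), rel=1e-8)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError, match="levels"):
            haar_mra(np.zeros(100), levels=7)


class TestPdLowfreqStd:
    def _series(self, x, rate=120.0):
        from flightload.ocular import NormalizedPupilSeries
        t = np.arange(x.size) / rate
        return NormalizedPupilSeries(t=t, pct_pd=x, baseline=4.0, eye="left")

    def test_constant_input_gives_zero(self):
        assert pd_lowfreq_std(self._series(np.full(512, 2.0))) == pytest.approx(0.0)

    def test_slow_sinusoid_std_is_amplitude_over_sqrt2(self):
        # 0.1 Hz sits inside the level-7 approximation band (0-0.469 Hz at 120 Hz)
        rate, dur, a = 120.0, 200.0, 3.0
        t = np.arange(0, dur, 1 / rate)
        x = a * np.sin(2 * np.pi * 0.1 * t)
        got = pd_lowfreq_std(self._series(x))
        assert got == pytest.approx(a / np.sqrt(2), rel=0.05)

    def test_ideal_lowpass_oracle_agrees_on_mixed_signal(self):
        rate, dur = 120.0, 200.0
        t = np.arange(0, dur, 1 / rate)
        x = 2.0 * np.sin(2 * np.pi * 0.1 * t) + 1.5 * np.sin(2 * np.pi * 7.0 * t)
        # oracle: keep only the level-7 band 0-0.469 Hz via DFT truncation
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, 1 / rate)
        spec[freqs > rate / 2**8] = 0.0
        oracle_std = np.std(np.fft.irfft(spec, x.size), ddof=1)
        got = pd_lowfreq_std(self._series(x))
        assert got == pytest.approx(oracle_std, rel=0.05)

    def test_scaling_input_scales_output(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1024).cumsum() / 30.0
        base = pd_lowfreq_std(self._series(x))
        assert pd_lowfreq_std(self._series(-2.5 * x)) == pytest.approx(
            2.5 * base, rel=1e-9
        )


# ---------------------------------------------------------------------------
# angular velocity and fixation detection


class TestAngularVelocity:
    def test_identical_vectors_give_zero(self):
        g = make_gaze(np.arange(5) / 120.0, np.zeros((5, 2)))
        _, vel = angular_velocity(g)
        np.testing.assert_allclose(vel, 0.0, atol=1e-9)

    def test_one_degree_step_at_120hz_is_120_deg_per_s(self):
        step = np.tan(np.radians(1.0))
        g = make_gaze([0.0, 1 / 120.0], [[0.0, 0.0], [step, 0.0]])
        _, vel = angular_velocity(g)
        assert vel[0] == pytest.approx(120.0, rel=1e-9)

    def test_antiparallel_vectors_are_180_deg(self):
        t = np.array([0.0, 1.0])
        dirs = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        g = GazeSeries(
            t=t, dir=dirs, pd_left=np.full(2, 3.0), pd_right=np.full(2, 3.0),
            valid=np.ones(2, bool),
        )
        _, vel = angular_velocity(g)
        assert vel[0] == pytest.approx(180.0, rel=1e-12)

    def test_duplicate_timestamps_rejected(self):
        # the series container already enforces strictly increasing time
        with pytest.raises(ValueError, match="increasing"):
            make_gaze([0.0, 0.1, 0.1], np.zeros((3, 2)))


class TestDetectFixations:
    def test_constant_gaze_is_one_long_fixation(self):
        t = np.arange(0, 10, 1 / 120)
        f = detect_fixations(make_gaze(t, np.zeros((t.size, 2))))
        assert len(f) == 1
        s, e = f.events[0]
        assert e - s == pytest.approx(10.0, abs=0.02)

    def test_five_planted_plateaus_are_recovered(self):
        rate = 120.0
        plane = []
        centers = [(-0.1, 0.0), (0.0, 0.1), (0.1, 0.0), (0.0, -0.1), (0.1, 0.1)]
        for cx, cy in centers:
            plane += [(cx, cy)] * 60  # 0.5 s plateau, zero jitter
        t = np.arange(len(plane)) / rate
        f = detect_fixations(make_gaze(t, plane))
        assert len(f) == 5

    def test_continuous_fast_motion_has_no_fixations(self):
        # sweep at 60 deg/s: every interval supra-threshold
        rate = 120.0
        t = np.arange(0, 2, 1 / rate)
        ang = np.radians(60.0) * t
        plane = np.column_stack([np.tan(ang - ang.mean()), np.zeros(t.size)])
        f = detect_fixations(make_gaze(t, plane))
        assert len(f) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_classifier(self, seed):
        g = random_gaze(np.random.default_rng(seed), n=300)
        ours = detect_fixations(g).events
        oracle = brute_force_fixations(g)
        assert len(ours) == len(oracle)
        for (s1, e1), (s2, e2) in zip(ours, oracle):
            assert s1 == pytest.approx(s2, abs=1e-12)
            assert e1 == pytest.approx(e2, abs=1e-12)

    def test_invalid_samples_are_skipped_not_split(self):
        # a blink inside a steady fixation must not split the event
        t = np.arange(0, 4, 1 / 120)
        valid = np.ones(t.size, bool)
        valid[200:230] = False
        f = detect_fixations(make_gaze(t, np.zeros((t.size, 2)), valid=valid))
        assert len(f) == 1


class TestFixationStats:
    def test_single_full_length_fixation(self):
        from flightload.ocular import FixationList
        f = FixationList(events=[(0.0, 10.0)], threshold=30.0, task_duration=10.0)
        rate, mean = fixation_stats(f)
        assert rate == pytest.approx(0.1)
        assert mean == pytest.approx(10.0)

    def test_rate_and_mean_arithmetic(self):
        from flightload.ocular import FixationList
        events = [(0, 2.0), (3, 4.5), (5, 6.5), (8, 10.0), (12, 13.0)]
        f = FixationList(events=events, threshold=30.0, task_duration=20.0)
        rate, mean = fixation_stats(f)
        assert rate == pytest.approx(0.25)
        assert mean == pytest.approx(8.0 / 5.0)

    def test_zero_fixations_flagged_missing(self):
        from flightload.ocular import FixationList
        f = FixationList(events=[], threshold=30.0, task_duration=20.0)
        rate, mean = fixation_stats(f)
        assert rate == 0.0
        assert np.isnan(mean)


# ---------------------------------------------------------------------------
# nearest-neighbour index


class TestNNI:
    def test_square_grid_gives_two(self):
        s = 0.3
        xx, yy = np.meshgrid(np.arange(10) * s, np.arange(10) * s)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        assert nni(pts, area=100 * s**2) == pytest.approx(2.0)

    def test_coincident_points_give_zero(self):
        pts = np.zeros((50, 2))
        assert nni(pts, area=1.0) == 0.0

    def test_uniform_points_approach_one(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 1, size=(2000, 2))
        assert nni(pts, area=1.0) == pytest.approx(1.0, abs=0.05)

    def test_tighter_clusters_lower_the_index(self):
        rng = np.random.default_rng(22)
        centers = rng.uniform(0, 1, size=(10, 2))
        vals = []
        for scale in (0.08, 0.04, 0.02, 0.01):
            pts = np.concatenate(
                [c + rng.normal(0, scale, size=(40, 2)) for c in centers]
            )
            vals.append(nni(pts, area=1.0))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            nni(np.zeros((10, 2)), area=0.0)


# ---------------------------------------------------------------------------
# shared invariances


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(-1e3, 1e3, allow_nan=False))
    def test_fixation_stats_invariant_to_time_shift(self, shift):
        g = random_gaze(np.random.default_rng(99), n=240)
        g_shift = GazeSeries(
            t=g.t + shift, dir=g.dir, pd_left=g.pd_left,
            pd_right=g.pd_right, valid=g.valid,
        )
        r1, m1 = fixation_stats(detect_fixations(g))
        r2, m2 = fixation_stats(detect_fixations(g_shift))
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert m1 == pytest.approx(m2, rel=1e-9, nan_ok=True)

    def test_lowfreq_std_invariant_to_constant_offset(self):
        from flightload.ocular import NormalizedPupilSeries
        rng = np.random.default_rng(8)
        x = rng.normal(size=512).cumsum() / 20.0
        t = np.arange(x.size) / 120.0
        s1 = NormalizedPupilSeries(t=t, pct_pd=x, baseline=4.0, eye="left")
        s2 = NormalizedPupilSeries(t=t, pct_pd=x + 42.0, baseline=4.0, eye="left")
        assert pd_lowfreq_std(s1) == pytest.approx(pd_lowfreq_std(s2), rel=1e-9)
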