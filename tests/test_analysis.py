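"""Analysis pipeline: bias calibration, affine registration, onset
detection, tracking, trace extraction, filtering, classification and
cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polcurve import (
    ChannelStack,
    EventSpec,
    FilterCriteria,
    MovieConfig,
    TrackParams,
    analyze_movie,
    bias_calibrate,
    bias_subtract,
    classify_event,
    cohort_stats,
    correlate_height_ps,
    detect_and_track,
    extract_traces,
    filter_events,
    fit_affine,
    match_to_truth,
    render_movie,
)
from polcurve.analysis import track_recovery
from polcurve.onsets import detect_onset
from polcurve.optics import planar_ps, render_channels, ps_ratio
from polcurve.geometry import build_surface, stage_sequence


class TestBiasCalibration:
    def test_constant_dark_frames(self):
        dark = np.full((30, 8, 8), 100.0)
        np.testing.assert_allclose(bias_calibrate(dark), 100.0)

    def test_subtract_bias_from_itself_gives_zero(self):
        rng = np.random.default_rng(0)
        dark = rng.poisson(100, size=(30, 8, 8)).astype(float)
        bias = bias_calibrate(dark)
        stack = ChannelStack(bias[None, None], ("clathrin",), 125.0)
        out = bias_subtract(stack, bias)
        np.testing.assert_allclose(out.frames, 0.0)

    def test_poisson_dark_frames_standard_error(self):
        """Bias from 30 Poisson(100) frames lands within 3 SE of 100 at
        every pixel (SE = sqrt(100/30))."""
        rng = np.random.default_rng(1)
        dark = rng.poisson(100, size=(30, 16, 16)).astype(float)
        bias = bias_calibrate(dark)
        assert np.abs(bias - 100.0).max() < 3.5 * np.sqrt(100 / 30)

    def test_shape_mismatch_raises(self):
        stack = ChannelStack(np.zeros((2, 1, 8, 8)), ("clathrin",), 125.0)
        with pytest.raises(ValueError):
            bias_subtract(stack, np.zeros((4, 4)))


class TestAffine:
    def test_identity(self):
        pts = np.array([[0.0, 0.0], [1, 0], [0, 1], [2, 3]])
        tf = fit_affine(pts, pts)
        np.testing.assert_allclose(tf.matrix, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tf.offset, 0.0, atol=1e-12)
        assert tf.rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered_exactly(self):
        pts = np.array([[0.0, 0.0], [10, 0], [0, 10], [10, 10]])
        tf = fit_affine(pts, pts + [5.0, -3.0])
        np.testing.assert_allclose(tf.offset, [5.0, -3.0], atol=1e-12)
        np.testing.assert_allclose(tf.matrix, np.eye(2), atol=1e-12)

    def test_rotation_scale_noise_free_and_noisy_rms(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(10, 2))
        ang = np.deg2rad(7.0)
        A = 1.02 * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        dst = pts @ A.T + [3.0, -1.0]
        tf = fit_affine(pts, dst)
        np.testing.assert_allclose(tf.matrix, A, atol=1e-9)
        assert tf.rms < 1e-9
        # least-squares theory: E[RMS] ~ sigma * sqrt(2 (n-3) / n) over reps
        sigma, n, reps = 0.5, 10, 300
        rms = []
        for _ in range(reps):
            noisy = dst + rng.normal(0, sigma, dst.shape)
            rms.append(fit_affine(pts, noisy).rms)
        expected = sigma * np.sqrt(2 * (n - 3) / n / 2)  # per-coordinate RMS
        assert np.mean(rms) == pytest.approx(sigma * np.sqrt((n - 3) / n), rel=0.1)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_affine(np.zeros((2, 2)), np.zeros((2, 2)))
        line = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(ValueError):
            fit_affine(line, line)


class TestOnsetDetection:
    def test_clean_step_found_at_step_frame(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(0, 1.0, 200)
        trace[50:100] += 30.0
        onset = detect_onset(trace, baseline_window=10, k=3, m=3)
        assert abs(onset - 50) <= 2  # changepoint refinement convention
        raw = detect_onset(trace, baseline_window=10, k=3, m=3, refine_k=None)
        assert raw == 50

    def test_pure_noise_false_positive_rate(self):
        """At k=5 a pure-noise trace yields no onset in >= 99% of reps."""
        rng = np.random.default_rng(4)
        hits = sum(
            detect_onset(rng.normal(0, 1, 120), baseline_window=10, k=5, m=3) is not None
            for _ in range(400)
        )
        assert hits / 400 <= 0.01

    def test_threshold_monotonicity_on_ramp(self):
        trace = np.concatenate([np.zeros(20), np.linspace(0, 30, 60)])
        trace += np.sin(np.arange(80)) * 1e-3  # break MAD degeneracy
        onsets = [
            detect_onset(trace, baseline_window=10, k=k, m=3, refine_k=None)
            for k in (2.0, 4.0, 8.0)
        ]
        assert onsets[0] <= onsets[1] <= onsets[2]

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            detect_onset(np.zeros(10), baseline_window=10, m=3)


class TestTracking:
    def _single_spot_movie(self, n=60, pos=(20.0, 25.0), on=20, off=45):
        rng = np.random.default_rng(5)
        frames = rng.poisson(50, size=(n, 1, 48, 48)).astype(float)
        xx, yy = np.mgrid[:48, :48]
        spot = 300 * np.exp(-((xx - pos[0]) ** 2 + (yy - pos[1]) ** 2) / (2 * 0.72**2))
        frames[on:off, 0] += spot
        return ChannelStack(frames, ("clathrin",), 125.0)

    def test_single_stationary_event_one_track(self):
        stack = self._single_spot_movie()
        tracks = detect_and_track(stack)
        spanning = [t for t in tracks if t.start <= 22 and t.end >= 42]
        assert len(spanning) == 1
        tr = spanning[0]
        assert np.hypot(tr.x_med - 20.0, tr.y_med - 25.0) < 1.0

    def test_two_events_no_identity_swap(self):
        rng = np.random.default_rng(6)
        frames = rng.poisson(50, size=(40, 1, 48, 48)).astype(float)
        xx, yy = np.mgrid[:48, :48]
        for pos in ((15.0, 15.0), (15.0, 25.0)):  # 10 px apart
            frames[5:35, 0] += 300 * np.exp(
                -((xx - pos[0]) ** 2 + (yy - pos[1]) ** 2) / (2 * 0.72**2)
            )
        tracks = detect_and_track(ChannelStack(frames, ("clathrin",), 125.0))
        long_tracks = [t for t in tracks if t.end - t.start > 20]
        assert len(long_tracks) == 2
        for t in long_tracks:
            assert t.x.std() < 0.5 and t.y.std() < 0.5  # stationary, no swaps

    def test_recovery_on_ground_truth_movie(self, small_movie):
        """>= 95% of non-abortive generated events are recovered as tracks."""
        stack = bias_subtract(small_movie["stack"], small_movie["bias"])
        tracks = detect_and_track(stack)
        assert track_recovery(tracks, small_movie["truth"]) >= 0.95


class TestExtractTraces:
    def test_planar_region_traces(self, optical, templates):
        mc = MovieConfig(field_px=32, n_frames=40, noise=False, seed=0, camera_offset=0.0)
        stack, _ = render_movie([], optical, mc)
        from polcurve.analysis import RawTrack

        tr = RawTrack(0, np.arange(40), np.full(40, 16.0), np.full(40, 16.0))
        et = extract_traces(stack, tr)
        # no clathrin anywhere: background-subtracted trace ~ 0
        np.testing.assert_allclose(et.intensity["clathrin"], 0.0, atol=1e-9)
        # planar membrane: ratio trace equals 2 cot^2(beta)
        np.testing.assert_allclose(et.ps, planar_ps(70.0), rtol=1e-9)

    def test_positive_step_at_event(self, small_movie):
        stack = bias_subtract(small_movie["stack"], small_movie["bias"])
        truth = small_movie["truth"]
        t = truth.iloc[0]
        from polcurve.analysis import RawTrack

        n = stack.n_frames
        tr = RawTrack(
            0,
            np.arange(int(t.clathrin_onset_frame), int(t.end_frame)),
            np.full(int(t.end_frame) - int(t.clathrin_onset_frame), float(t.x_px)),
            np.full(int(t.end_frame) - int(t.clathrin_onset_frame), float(t.y_px)),
        )
        et = extract_traces(stack, tr)
        pre = et.intensity["clathrin"][: int(t.clathrin_onset_frame) - 2]
        during = et.intensity["clathrin"][
            int(t.clathrin_onset_frame) + 5 : int(t.end_frame) - 2
        ]
        assert during.mean() > pre.mean() + 5 * pre.std()


def _make_track(cl, ps, dyn, start, end, dt=2.0):
    from polcurve.analysis import EventTrack

    n = len(cl)
    return EventTrack(
        track_id=0, x=10.0, y=10.0, start=start, end=end, frame_interval=dt,
        intensity={"clathrin": cl, "dynamin": dyn}, raw={}, ps=ps,
    )


class TestFilterEvents:
    def _noise(self, rng, n=120):
        return rng.normal(0, 1, n)

    def test_censored_track_rejected(self):
        rng = np.random.default_rng(7)
        tr = _make_track(self._noise(rng), self._noise(rng), self._noise(rng), 0, 40)
        kept, rejected = filter_events([tr], n_frames=120)
        assert not kept and rejected[0].reject_reason == "censored"

    def test_overlapping_neighbors_both_rejected(self):
        rng = np.random.default_rng(8)
        a = _make_track(self._noise(rng), self._noise(rng), self._noise(rng), 20, 60)
        b = _make_track(self._noise(rng), self._noise(rng), self._noise(rng), 30, 70)
        b.x, b.y = a.x + 2.0, a.y + 2.0  # within the 5 px isolation radius
        b.track_id = 1
        kept, rejected = filter_events([a, b], n_frames=120)
        assert not kept
        assert {t.reject_reason for t in rejected} == {"not_isolated"}

    def test_no_dynamin_rejected(self):
        rng = np.random.default_rng(9)
        cl = self._noise(rng)
        cl[30:38] += 20
        tr = _make_track(cl, self._noise(rng), self._noise(rng), 30, 38)
        kept, rejected = filter_events([tr], n_frames=120)
        assert not kept and rejected[0].reject_reason == "no_dynamin"

    def test_every_rejection_has_exactly_one_reason(self, small_movie):
        stack = bias_subtract(small_movie["stack"], small_movie["bias"])
        tracks = detect_and_track(stack)
        traces = [extract_traces(stack, t) for t in tracks]
        kept, rejected = filter_events(traces, n_frames=stack.n_frames)
        assert len(kept) + len(rejected) == len(traces)
        assert all(isinstance(t.reject_reason, str) for t in rejected)
        assert all(t.reject_reason is None for t in kept)


class TestClassification:
    def _render_single(self, optical, templates, label, prebend, lag):
        mc = MovieConfig(field_px=48, n_frames=120, noise=False, seed=0,
                         camera_offset=0.0)
        spec = EventSpec(label, 3000.0, 3000.0, 60.0, 120.0, lag, prebend,
                         20.0, 2.0, 140.0)
        stack, truth = render_movie([spec], optical, mc, templates=templates)
        from polcurve.analysis import RawTrack

        t = truth.iloc[0]
        frames = np.arange(int(t.clathrin_onset_frame), int(t.end_frame))
        tr = RawTrack(0, frames, np.full(len(frames), float(t.x_px)),
                      np.full(len(frames), float(t.y_px)))
        # tiny noise floor so MAD thresholds are well-defined on clean traces
        rng = np.random.default_rng(0)
        stack.frames[:] += rng.normal(0, 1e-3, stack.frames.shape)
        et = extract_traces(stack, tr)
        return classify_event(et), et

    def test_synthetic_class1(self, optical, templates):
        label, _ = self._render_single(optical, templates, "class1", 0.0, 0.0)
        assert label == "class1"

    def test_synthetic_class2(self, optical, templates):
        label, et = self._render_single(optical, templates, "class2", 1.0, 25.5)
        assert label == "class2"
        assert et.lag_cl_to_ps == pytest.approx(25.5, abs=4.0)

    def test_synthetic_class3(self, optical, templates):
        label, _ = self._render_single(optical, templates, "class3", 0.5, 25.5)
        assert label == "class3"

    def test_no_ps_onset_is_abortive(self):
        rng = np.random.default_rng(11)
        cl = rng.normal(0, 1, 120)
        cl[30:40] += 25
        ps = rng.normal(0.26, 0.002, 120)
        dyn = rng.normal(0, 1, 120)
        tr = _make_track(cl, ps, dyn, 30, 40)
        assert classify_event(tr) == "abortive"


class TestCohortStats:
    def test_recovered_population_statistics(self, analyzed_acceptance, acceptance_movie):
        """On a 220-event movie the per-class lifetime means and the
        class-2/3 lag excess recover the generator inputs."""
        table = analyzed_acceptance["table"]
        df = table[table["class_label"].str.startswith("class")]
        summary = cohort_stats(df)
        per = summary["per_class"]
        m1 = per.loc["class1", ("clathrin_lifetime", "mean")]
        n1 = per.loc["class1", ("clathrin_lifetime", "count")]
        sd1 = per.loc["class1", ("clathrin_lifetime", "std")]
        assert abs(m1 - 80.0) < 2 * sd1 / np.sqrt(n1) + 2.0
        assert summary["lag_differences"]["lag_cl_to_ps"] == pytest.approx(25.5, abs=3.0)
        # class 1 lifetimes shorter than class 2/3 (the delayed-bending delay)
        assert summary["lifetime_test"]["p"] < 0.05

    def test_identical_distributions_rarely_rejected(self):
        """Type-I behavior of the lifetime test: ~5% rejections under the
        null (quick check; the full calibration runs in acceptance)."""
        rng = np.random.default_rng(12)
        rej = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(100, 30, 40)
            b = rng.normal(100, 30, 60)
            if stats.mannwhitneyu(a, b, alternative="two-sided").pvalue < 0.05:
                rej += 1
        assert 0.01 < rej / reps < 0.10

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cohort_stats(pd.DataFrame(columns=["class_label", "clathrin_lifetime"]))


class TestHeightCorrelation:
    def test_perfectly_monotone(self):
        h = np.arange(10.0)
        rho, p = correlate_height_ps(h, h**2, n_permutations=500, seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_independent_pairs_small_rho(self):
        rng = np.random.default_rng(13)
        big = 0
        for _ in range(100):
            rho, _ = correlate_height_ps(
                rng.normal(size=100), rng.normal(size=100), n_permutations=0 + 10, seed=0
            )
            big += abs(rho) >= 0.3
        assert big <= 1

    def test_forward_model_heights_vs_ps(self, optical):
        """Apex heights and rendered P/S from matched fixed-radius stages
        correlate strongly (noise off)."""
        heights, ps_vals = [], []
        for stage in stage_sequence("class1", 10):
            surf = build_surface(stage, grid=2.0, extent=1000.0)
            _, p, s = render_channels(surf, optical)
            c = p.pixels.shape[0] // 2
            heights.append(stage.apex_height)
            ps_vals.append(ps_ratio(p, s).pixels[c, c])
        rho, p_val = correlate_height_ps(
            np.array(heights), np.array(ps_vals), n_permutations=2000, seed=1
        )
        assert rho > 0.9
        assert p_val < 0.01

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError):
            correlate_height_ps(np.ones(10), np.arange(10.0))


class TestEndToEnd:
    def test_no_curvature_before_clathrin(self, analyzed_acceptance):
        """No kept track shows a P/S onset preceding the clathrin onset
        beyond the coincidence window."""
        table = analyzed_acceptance["table"]
        kept = table[table["class_label"].str.startswith("class")]
        lags = kept["ps_onset"].astype(float) - kept["clathrin_onset"].astype(float)
        assert (lags >= -2).all()

    def test_filter_partition(self, analyzed_acceptance):
        table = analyzed_acceptance["table"]
        assert len(table) > 0
        labels = set(table["class_label"])
        assert labels <= {"class1", "class2", "class3", "abortive", "rejected"}
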