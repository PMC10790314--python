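"""Transient detection/featurization tests against explicit oracles."""
import numpy as np
import pytest

from nodoscope import synth
from nodoscope.synth import CLASS_PRESETS, draw_kernel, draw_kernels, render_trace
from nodoscope.transients import (
    ArtifactParams,
    DetectionParams,
    count_subpeaks,
    detect_and_featurize,
    detect_artifacts,
    detect_transients,
    featurize,
    remove_artifact_transients,
)

from reference_impls import (
    naive_count_subpeaks,
    naive_detect,
    naive_features,
)

FPS = 20.0


def _alt_baseline(n=200, sd=0.5):
    """Deterministic 'noise': alternating +/-sd has mean 0, SD exactly sd."""
    return sd * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)


def _params(**kw):
    kw.setdefault("baseline_window", (0.0, 10.0))
    return DetectionParams(**kw)


class TestDetect:
    def test_pure_noise_trace_yields_no_events(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 0.5, size=2000)
        assert detect_transients(trace, FPS, _params()) == []

    def test_flat_trace_rejected_for_zero_baseline_sd(self):
        with pytest.raises(ValueError, match="baseline SD"):
            detect_transients(np.zeros(400), FPS, _params())

    def test_single_kernel_amplitude_recovered_exactly(self):
        # baseline with known mean 0 / SD 0.5, then a noiseless bump of 10
        trace = np.zeros(600)
        trace[:200] = _alt_baseline()
        peak = np.concatenate([np.linspace(0, 10, 21), np.linspace(10, 0, 41)[1:]])
        trace[300 : 300 + peak.size] = peak
        events = detect_transients(trace, FPS, _params())
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(10.0)
        assert events[0].t_peak == pytest.approx(320 / FPS)

    def test_two_separated_kernels_stay_two_events(self):
        trace = np.zeros(1200)
        trace[:200] = _alt_baseline()
        bump = np.concatenate([np.linspace(0, 8, 11), np.linspace(8, 0, 11)[1:]])
        trace[400 : 400 + bump.size] = bump
        trace[500 : 500 + bump.size] = bump  # 5 s apart > gap_merge
        events = detect_transients(trace, FPS, _params())
        assert len(events) == 2

    def test_raising_threshold_never_adds_events(self):
        # well-separated events (separation >> duration + gap_merge, so
        # event merging cannot interact with the threshold sweep)
        from nodoscope.synth import _kernel_from_features

        rng = np.random.default_rng(1)
        for _ in range(20):
            ks = [
                _kernel_from_features(
                    rng.uniform(4, 40), rng.uniform(3, 8), rng.integers(1, 4), rng
                )
                for _ in range(2)
            ]
            trace = render_trace(
                [k.shifted(15 + 30 * i) for i, k in enumerate(ks)],
                1400, FPS, noise_sd=0.5, rng=rng,
            )
            counts = [
                len(detect_transients(trace, FPS, _params(k_sd=k)))
                for k in (2.0, 3.0, 4.0, 6.0)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_matches_naive_reference_on_random_traces(self):
        """Oracle equivalence on 150 random synthetic traces (the full
        1000-trace sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(2)
        params = _params()
        for i in range(150):
            preset = list(CLASS_PRESETS.values())[i % 3]
            ks = draw_kernels(preset, rng.integers(0, 3), rng)
            trace = render_trace(
                [k.shifted(12 + rng.uniform(0, 30)) for k in ks],
                1600, FPS, noise_sd=0.5, rng=rng,
            )
            got = detect_transients(trace, FPS, params)
            want, mean, sd, theta = naive_detect(trace, FPS, params)
            assert len(got) == len(want)
            for g, (s, p, e) in zip(got, want):
                amp, dur, area, rise, decay = naive_features(trace, FPS, s, p, e, mean)
                assert g.t_start == pytest.approx(s / FPS, abs=1e-12)
                assert g.t_peak == pytest.approx(p / FPS, abs=1e-12)
                assert g.t_end == pytest.approx(e / FPS, abs=1e-12)
                assert g.amplitude == pytest.approx(amp, rel=1e-9)
                assert g.integral == pytest.approx(area, rel=1e-9)
                assert g.rise == pytest.approx(rise, rel=1e-9)
                assert g.decay == pytest.approx(decay, rel=1e-9)
                n = naive_count_subpeaks(
                    trace, FPS, s, e, theta, params.peak_prominence_sd * sd,
                    params.min_separation, params.count_smooth_s,
                )
                assert g.n_peaks == n


class TestSubpeaks:
    def _count(self, seg, **kw):
        trace = np.concatenate([_alt_baseline(), seg, np.zeros(40)])
        kw.setdefault("theta", 1.5)
        kw.setdefault("prominence", 0.5)
        kw.setdefault("min_separation", 0.5)
        kw.setdefault("smooth_s", 0.0)
        return count_subpeaks(trace, FPS, 200, 200 + seg.size - 1, **kw)

    def test_single_smooth_bump_counts_one(self):
        seg = np.concatenate([np.linspace(0, 8, 30), np.linspace(8, 0, 30)[1:]])
        assert self._count(seg) == 1

    def test_three_equal_bumps_count_three(self):
        bump = np.concatenate([np.linspace(1, 8, 15), np.linspace(8, 1, 15)[1:]])
        seg = np.concatenate([bump, bump, bump])
        assert self._count(seg) == 3

    def test_low_prominence_shoulder_not_counted(self):
        up = np.linspace(0, 8, 40)
        up[20:24] += np.array([0.3, 0.6, 0.3, 0.0])  # bump of prominence ~0.1
        seg = np.concatenate([up, np.linspace(8, 0, 40)[1:]])
        assert self._count(seg, prominence=0.5) == 1
        assert self._count(seg, prominence=0.05, min_separation=0.05) == 2


class TestFeaturize:
    def test_symmetric_triangle_geometry(self):
        # triangle amplitude 6, half-width 1 s on a zero baseline
        w = int(FPS)
        tri = np.concatenate([np.linspace(0, 6, w + 1), np.linspace(6, 0, w + 1)[1:]])
        trace = np.concatenate([np.zeros(100), tri, np.zeros(100)])
        t = featurize(
            trace, FPS, 100, 100 + w, 100 + 2 * w,
            baseline_mean=0.0, baseline_sd=0.5, params=_params(),
        )
        assert t.amplitude == pytest.approx(6.0)
        assert t.duration == pytest.approx(2.0)
        assert t.rise == pytest.approx(6.0)
        assert t.decay == pytest.approx(6.0)
        assert t.integral == pytest.approx(6.0)  # A*w = 6*1

    def test_instant_drop_decay_uses_one_frame(self):
        w = int(FPS)
        trace = np.concatenate([np.zeros(100), np.linspace(0, 6, w + 1), np.zeros(100)])
        t = featurize(
            trace, FPS, 100, 100 + w, 100 + w,
            baseline_mean=0.0, baseline_sd=0.5, params=_params(),
        )
        # single-frame slope: one linspace step over one frame interval
        assert t.decay == pytest.approx((6.0 / 20) * FPS)

    def test_noiseless_kernel_features_match_analytic(self):
        """Rendered kernel -> detector features equal the closed-form
        kernel features up to frame quantisation."""
        rng = np.random.default_rng(5)
        for seed in range(12):
            k = draw_kernel(CLASS_PRESETS["capsaicin"], seed).shifted(30.0)
            trace = render_trace([k], 1600, FPS)
            trace[:400] = _alt_baseline(400, sd=0.05)
            events = detect_transients(trace, FPS, _params(baseline_window=(0, 20)))
            assert len(events) == 1
            got = events[0]
            want = k.analytic_features()
            dt = 1.0 / FPS
            assert got.amplitude == pytest.approx(want["amplitude"], rel=0.05)
            assert got.duration == pytest.approx(want["duration"], abs=3 * dt)
            assert got.n_peaks == want["n_peaks"]
            assert got.integral == pytest.approx(want["integral"], rel=0.05)


class TestArtifacts:
    def _events(self, peaks_by_roi):
        from nodoscope.containers import Transient

        out = {}
        for rid, peaks in peaks_by_roi.items():
            out[rid] = [
                Transient(
                    roi_id=rid, t_start=p - 0.2, t_peak=p, t_end=p + 0.2,
                    amplitude=5.0, duration=0.4, n_peaks=1, integral=1.0,
                    rise=1.0, decay=1.0,
                )
                for p in peaks
            ]
        return out

    def test_three_of_ten_coincident_flagged(self):
        ev = self._events({f"r{i}": ([50.0] if i < 3 else [10.0 + i]) for i in range(10)})
        flagged = detect_artifacts(ev, n_rois=10, fps=FPS)
        assert any(a <= 50.0 <= b for a, b in flagged)

    def test_two_of_ten_not_flagged(self):
        ev = self._events({f"r{i}": ([50.0] if i < 2 else [100.0 + 3 * i]) for i in range(10)})
        assert detect_artifacts(ev, n_rois=10, fps=FPS) == []

    def test_exact_threshold_fraction_is_flagged(self):
        # 3/10 = 0.30 exactly: inclusive rule flags it
        ev = self._events({f"r{i}": ([20.0] if i < 3 else [60.0 + 2 * i]) for i in range(10)})
        params = ArtifactParams(coincidence_fraction=0.30)
        assert any(a <= 20.0 <= b for a, b in detect_artifacts(ev, 10, FPS, params))

    def test_tiny_population_guarded(self):
        ev = self._events({"r0": [5.0]})
        assert detect_artifacts(ev, n_rois=1, fps=FPS) == []
        # without the guard the single ROI trips the fraction rule
        params = ArtifactParams(min_rois=1)
        assert detect_artifacts(ev, n_rois=1, fps=FPS, params=params) != []

    def test_removal_matches_set_difference_oracle(self):
        ev = self._events({"a": [5.0, 50.0], "b": [50.2], "c": [80.0]})
        flagged = [(49.5, 51.0)]
        kept, removed = remove_artifact_transients(ev, flagged)
        assert [t.t_peak for t in kept["a"]] == [5.0]
        assert [t.t_peak for t in removed["a"]] == [50.0]
        assert kept["b"] == []
        assert [t.t_peak for t in kept["c"]] == [80.0]

    def test_no_flags_is_identity(self):
        ev = self._events({"a": [5.0], "b": [9.0]})
        kept, removed = remove_artifact_transients(ev, [])
        assert kept == ev
        assert all(v == [] for v in removed.values())

    def test_injected_global_artifacts_are_flagged(self):
        """Every injected breathing bump hitting >= 30% of ROIs is
        caught by the coincidence rule on the detected transients."""
        noise = synth.NoiseModel(trace_noise_sd=0.5, artifact_prob_per_min=4.0)
        rng = np.random.default_rng(11)
        kernels = [
            [k.shifted(70 + rng.uniform(0, 40))]
            for k in draw_kernels(CLASS_PRESETS["capsaicin"], 12, rng)
        ]
        traces, truth = synth.render_trace_set(
            kernels, 3000, FPS, noise, rng, inject_artifacts=True
        )
        assert len(truth["artifact_times"]) >= 1
        events = detect_and_featurize(traces, FPS, _params(baseline_window=(0, 55)))
        flagged = detect_artifacts(events, n_rois=12, fps=FPS)
        times = truth["artifact_times"]
        for t0 in times:
            if np.sum(np.abs(times - t0) < 2.5) > 1:
                continue  # bumps closer than gap_merge fuse into one event
            t_pk = t0 + 0.15
            assert any(a - 0.2 <= t_pk <= b + 0.2 for a, b in flagged)
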