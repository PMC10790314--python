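"""Source-extraction tests on ground-truthed synthetic movies."""
import numpy as np
import pytest

from nodoscope import synth
from nodoscope.containers import Movie, ROISet
from nodoscope.preprocess import compute_dff
from nodoscope.sources import (
    ExtractParams,
    apply_fixed_rois,
    correlation_pnr_images,
    load_roiset,
    match_rois_to_truth,
    merge_rois,
    review_rois,
    save_roiset,
    seed_and_segment,
)


def _neuron_movie(n=1, noise_sd=0.0, T=400, dims=(54, 44), seed=0, amps=None):
    """dF/F movie with Gaussian somata and clean pulse traces."""
    rng = np.random.default_rng(seed)
    H, W = dims
    cents = [(10.0 + 14 * (i % 3), 10.0 + 14 * (i // 3)) for i in range(n)]
    fps_ = np.stack([synth.gaussian_footprint(dims, c, 10.0) for c in cents])
    traces = np.zeros((n, T))
    for i in range(n):
        a = 20.0 if amps is None else amps[i]
        on = 100 + 60 * i
        traces[i, on : on + 40] = a * np.hanning(40)
    data = np.einsum("nt,nhw->thw", traces, fps_)
    if noise_sd:
        data += rng.normal(0, noise_sd, size=data.shape)
    return Movie(data=data, fps=20.0, scale_tag="dff"), fps_, traces, np.array(cents)


class TestCorrelationPnr:
    def test_iid_noise_has_near_zero_correlation(self):
        rng = np.random.default_rng(0)
        movie = Movie(data=rng.normal(size=(1000, 12, 12)), fps=20, scale_tag="dff")
        corr, _ = correlation_pnr_images(movie)
        assert np.abs(corr).mean() < 0.05

    def test_noiseless_neuron_correlates_perfectly_inside_footprint(self):
        movie, fps_, traces, cents = _neuron_movie(1)
        corr, _ = correlation_pnr_images(movie)
        core = fps_[0] > 0.5
        assert corr[core].min() > 0.999

    def test_pnr_of_flat_trace_with_single_spike(self):
        # spike of 10x the noise SD on one pixel
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1.0, size=(1000, 5, 5))
        data[500, 2, 2] += 10.0
        _, pnr = correlation_pnr_images(Movie(data=data, fps=20, scale_tag="dff"))
        assert pnr[2, 2] == pytest.approx(10.0, rel=0.25)


class TestSeedAndSegment:
    def test_well_separated_neurons_recovered(self):
        movie, fps_, traces, cents = _neuron_movie(5, noise_sd=0.05, seed=2)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        assert roiset.n_rois == 5
        recall, precision, pairs = match_rois_to_truth(roiset, cents, tol_px=2.0)
        assert recall == 1.0 and precision == 1.0

    def test_impossible_correlation_threshold_finds_nothing(self):
        rng = np.random.default_rng(3)
        movie = Movie(data=rng.normal(size=(300, 20, 20)), fps=20, scale_tag="dff")
        roiset = seed_and_segment(movie, ExtractParams(min_corr=0.999, min_pnr=4))
        assert roiset.n_rois == 0

    def test_adjacent_identical_neurons_merge(self):
        H = W = 30
        fp1 = synth.gaussian_footprint((H, W), (15.0, 14.0), 10.0)
        fp2 = synth.gaussian_footprint((H, W), (15.0, 15.0), 10.0)
        tr = np.zeros(300)
        tr[100:140] = 20 * np.hanning(40)
        data = np.einsum("t,hw->thw", tr, fp1 + fp2)
        data += np.random.default_rng(4).normal(0, 0.02, size=data.shape)
        movie = Movie(data=data, fps=20, scale_tag="dff")
        roiset = seed_and_segment(movie, ExtractParams(gSig=2, gSiz=15))
        assert roiset.n_rois == 1

    def test_default_fixture_recall_and_precision(self, movie_fixture):
        """>= 90% recall and precision against generator truth on the
        default 10-neuron movie (jitter-free extraction path)."""
        movie, truth, _ = movie_fixture
        from nodoscope.preprocess import motion_correct_rigid

        corrected, _ = motion_correct_rigid(movie, (0, 100))
        dff = compute_dff(corrected)
        roiset = seed_and_segment(dff)
        recall, precision, _ = match_rois_to_truth(
            roiset, truth["centroids"], tol_px=6.0
        )
        assert recall >= 0.9
        assert precision >= 0.9


class TestMerge:
    def _set(self, fps_, traces):
        return ROISet(footprints=fps_, traces=traces)

    def test_disjoint_footprints_unchanged(self):
        fp = np.zeros((2, 10, 10))
        fp[0, 2, 2] = 1.0
        fp[1, 7, 7] = 1.0
        tr = np.tile(np.sin(np.linspace(0, 6, 50)), (2, 1))
        out = merge_rois(self._set(fp, tr), 0.999)
        assert out.n_rois == 2

    def test_duplicated_roi_collapses(self):
        fp = np.zeros((2, 10, 10))
        fp[:, 3, 3] = 1.0
        tr = np.tile(np.sin(np.linspace(0, 6, 50)), (2, 1))
        out = merge_rois(self._set(fp, tr), 0.999)
        assert out.n_rois == 1

    def test_transitive_chain_merges_to_one(self):
        # A overlaps B, B overlaps C, A and C disjoint; identical traces
        fp = np.zeros((3, 10, 10))
        fp[0, 2, 2:4] = 1.0
        fp[1, 2, 3:6] = 1.0
        fp[2, 2, 5:8] = 1.0
        tr = np.tile(np.sin(np.linspace(0, 6, 50)), (3, 1))
        out = merge_rois(self._set(fp, tr), 0.999)
        assert out.n_rois == 1

    def test_merge_is_idempotent(self):
        fp = np.zeros((3, 10, 10))
        fp[0, 2, 2:4] = 1.0
        fp[1, 2, 3:6] = 1.0
        fp[2, 7, 5:8] = 1.0
        rng = np.random.default_rng(5)
        tr = np.vstack([np.sin(np.linspace(0, 6, 50))] * 2 + [rng.normal(size=50)])
        once = merge_rois(self._set(fp, tr), 0.999)
        twice = merge_rois(once, 0.999)
        assert once.n_rois == twice.n_rois
        assert np.allclose(once.footprints, twice.footprints)


class TestFixedRois:
    def test_same_movie_reproduces_traces(self):
        movie, fps_, traces, cents = _neuron_movie(3, noise_sd=0.05, seed=6)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        again = apply_fixed_rois(movie, roiset)
        assert np.allclose(again.traces, roiset.traces)
        assert again.ids == roiset.ids

    def test_traces_linear_in_movie_intensity(self):
        movie, fps_, traces, cents = _neuron_movie(2, noise_sd=0.05, seed=7)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        doubled = apply_fixed_rois(movie.copy_with(data=movie.data * 2), roiset)
        assert np.allclose(doubled.traces, 2 * roiset.traces)

    def test_dimension_mismatch_rejected(self):
        movie, *_ = _neuron_movie(1)
        rs = ROISet(footprints=np.ones((1, 8, 8)), traces=np.zeros((1, movie.n_frames)))
        with pytest.raises(ValueError, match="match"):
            apply_fixed_rois(movie, rs)

    def test_truth_footprints_recover_traces_on_movie_fixture(self, movie_fixture):
        """Footprint-weighted readout of the dF/F movie correlates > 0.95
        with the generating traces (events shorter than the dF/F bin)."""
        movie, truth, _ = movie_fixture
        from nodoscope.preprocess import motion_correct_rigid

        corrected, _ = motion_correct_rigid(movie, (0, 100))
        dff = compute_dff(corrected)
        n = truth["footprints"].shape[0]
        rs = ROISet(footprints=truth["footprints"], traces=np.zeros((n, movie.n_frames)))
        out = apply_fixed_rois(dff, rs)
        for i in range(n):
            r = np.corrcoef(out.traces[i], truth["traces"][i])[0, 1]
            assert r > 0.95


class TestReview:
    def test_reject_all_empties_downstream(self):
        movie, fps_, traces, cents = _neuron_movie(3, noise_sd=0.05, seed=8)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        out, log = review_rois(roiset, {rid: False for rid in roiset.ids})
        kept = out.subset(np.flatnonzero(out.accepted))
        assert kept.n_rois == 0
        assert len(log) == roiset.n_rois

    def test_no_decisions_keeps_flags(self):
        movie, *_ = _neuron_movie(2, noise_sd=0.05, seed=9)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        out, log = review_rois(roiset, {})
        assert np.array_equal(out.accepted, roiset.accepted)
        assert log == []

    def test_unknown_id_rejected(self):
        movie, *_ = _neuron_movie(1)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        with pytest.raises(KeyError):
            review_rois(roiset, {"nope": True})

    def test_rejected_roi_excluded_from_feature_rows(self):
        from nodoscope.containers import StimulusEvent
        from nodoscope.responders import build_feature_table, classify_responders
        from nodoscope.transients import DetectionParams, detect_and_featurize

        movie, fps_, traces, cents = _neuron_movie(
            5, noise_sd=0.3, T=2400, seed=10, amps=[20, 25, 30, 35, 40]
        )
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        assert roiset.n_rois == 5
        reject = roiset.ids[2]
        reviewed, _ = review_rois(roiset, {reject: False})
        kept = reviewed.subset(np.flatnonzero(reviewed.accepted))
        det = DetectionParams(baseline_window=(0.0, 4.0))
        events = detect_and_featurize(kept.traces, movie.fps, det, ids=kept.ids)
        ev = StimulusEvent("stim", onset=4.5, post_window=115.0, pre_window=4.5)
        tab = build_feature_table(
            classify_responders(events, ev, traces=kept.traces, fps=movie.fps)
        )
        assert reject not in set(tab.roi_id)
        assert len(set(tab.roi_id)) == 4


class TestRoundTrip:
    def test_hdf5_roundtrip(self, tmp_path):
        movie, *_ = _neuron_movie(2, noise_sd=0.05, seed=11)
        roiset = seed_and_segment(movie, ExtractParams(gSig=4, gSiz=15))
        p = tmp_path / "rois.h5"
        save_roiset(roiset, p)
        back = load_roiset(p)
        assert back.ids == roiset.ids
        assert np.array_equal(back.footprints, roiset.footprints)
        assert np.array_equal(back.traces, roiset.traces)
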