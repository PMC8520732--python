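"""Marker episodes, event timing, alignment, progress, and mobility."""

import numpy as np
import pytest

from aggrephagy.detection import ParticleDetection
from aggrephagy.events import (
    MarkerEpisode,
    align_traces,
    anchor_frame,
    dfcp1_acidification_interval,
    estimate_mobility_switch,
    mobility_by_phase,
    ratio_progress_at_event,
    rab7_accumulation_ensemble,
    score_marker_presence,
    stx17_dwell_time,
)
from aggrephagy.sim import (
    MotionScript,
    SpectralModel,
    simulate_acidification_trace,
    simulate_marker_trace,
    simulate_positions,
)
from aggrephagy.tracking import Trace, Track, frame_displacements


class TestEpisodeScoring:
    def test_clean_boxcar(self):
        v = np.zeros(60)
        v[10:31] = 1.0
        (ep,) = score_marker_presence(v)
        assert (ep.start_frame, ep.end_frame) == (10, 30)
        assert ep.n_frames == 21

    def test_single_frame_dropout_bridged(self):
        v = np.zeros(60)
        v[10:31] = 1.0
        v[20] = 0.3
        (ep,) = score_marker_presence(v)
        assert (ep.start_frame, ep.end_frame) == (10, 30)

    def test_two_frame_dropout_splits(self):
        v = np.zeros(60)
        v[10:31] = 1.0
        v[20:22] = 0.1
        eps = score_marker_presence(v)
        assert len(eps) == 2

    def test_below_threshold_never_scores(self):
        assert score_marker_presence(np.full(30, 0.2)) == []
        assert score_marker_presence(np.zeros(30)) == []

    def test_min_frames_filters_blips(self):
        v = np.zeros(30)
        v[5] = 1.0
        assert score_marker_presence(v, min_frames=2) == []

    def test_raising_on_frac_never_lengthens(self):
        rng = np.random.default_rng(0)
        v = np.clip(np.convolve(rng.uniform(0, 1, 80), np.ones(5) / 5, mode="same"), 0, 1)
        v[20:50] += 0.5
        v = v / v.max()
        prev = None
        for on in (0.3, 0.5, 0.7, 0.9):
            eps = score_marker_presence(v, on_frac=on)
            total = sum(e.n_frames for e in eps)
            if prev is not None:
                assert total <= prev
            prev = total


class TestDwell:
    def test_arithmetic(self):
        ep = MarkerEpisode("stx17", 10, 30)
        assert stx17_dwell_time(ep, 20.0) == pytest.approx(7.0)
        assert stx17_dwell_time(MarkerEpisode("stx17", 5, 5), 20.0) == pytest.approx(1 / 3)


def _sigmoid_trace(onset=30, duration=10, n=60, marker=None, model=None):
    model = model or SpectralModel()
    ratio = simulate_acidification_trace(onset, duration, n, model)
    return Trace.from_series(ratio, marker)


class TestInterval:
    def test_constructed_crossings(self):
        # DFCP1 drops-and-stays below 0.7 at frame 30; ratio below 0.8 at 51
        n = 70
        marker = np.zeros(n)
        marker[10:30] = 1.0
        marker[30:] = 0.1
        ratio = np.full(n, 0.9)
        ratio[51:] = 0.3
        trace = Trace.from_series(ratio, marker)
        res = dfcp1_acidification_interval(trace)
        assert res.valid
        assert (res.t_dfcp1_frame, res.t_acid_frame) == (30, 51)
        assert res.minutes == pytest.approx(7.0)

    def test_monotone_rising_marker_excluded(self):
        n = 60
        marker = np.linspace(0, 1, n)
        ratio = np.full(n, 0.9)
        ratio[40:] = 0.3
        res = dfcp1_acidification_interval(Trace.from_series(ratio, marker))
        assert not res.valid and res.reason == "no_dfcp1_release"

    def test_no_acidification_excluded(self):
        n = 60
        marker = np.zeros(n)
        marker[10:30] = 1.0
        res = dfcp1_acidification_interval(Trace.from_series(np.full(n, 0.9), marker))
        assert not res.valid and res.reason == "no_acidification"

    def test_negative_interval_reported_signed(self):
        n = 70
        marker = np.zeros(n)
        marker[10:50] = 1.0
        marker[50:] = 0.1
        ratio = np.full(n, 0.9)
        ratio[20:] = 0.3
        res = dfcp1_acidification_interval(Trace.from_series(ratio, marker))
        assert res.valid and res.minutes < 0


class TestAlignment:
    def test_identical_traces_zero_sd(self):
        traces = [_sigmoid_trace() for _ in range(5)]
        ens = align_traces(traces, "ratio_half_drop")
        contributing = ens.n == 5
        assert np.all(ens.sd_ratio[contributing] < 1e-12)
        assert np.allclose(
            ens.mean_ratio[contributing],
            traces[0].ratio[np.isin(traces[0].frames - ens.anchor_frames[0],
                                    ens.rel_frames[contributing])],
        )

    def test_half_drop_anchor_matches_scripted_midpoint(self):
        model = SpectralModel()
        for onset, duration in [(20, 10), (30, 8), (15, 6)]:
            trace = _sigmoid_trace(onset, duration, 60, model=model)
            # scripted midpoint: first frame at or below the half-way ratio
            mid = (model.ratio_neutral + model.ratio_acidic) / 2
            expected = int(np.argmax(trace.ratio <= mid + 1e-12))
            assert anchor_frame(trace, "ratio_half_drop") == expected

    def test_stx17_anchor_is_first_absent_frame(self):
        trace = _sigmoid_trace()
        ep = MarkerEpisode("stx17", 10, 30)
        assert anchor_frame(trace, "stx17_disappearance", ep) == 31

    def test_shifted_step_copies_reproduce_template(self):
        # time-shifted copies of one step function align into the same
        # step with the transition at frame 0 and zero s.d.
        traces = []
        for shift in (0, 3, 7, 12):
            ratio = np.full(80, 0.9)
            ratio[40 + shift:] = 0.2
            traces.append(Trace.from_series(ratio))
        ens = align_traces(traces, "ratio_half_drop")
        full = ens.n == len(traces)
        assert np.all(ens.sd_ratio[full] < 1e-12)
        zero_idx = int(np.argmax(ens.rel_frames == 0))
        assert ens.mean_ratio[zero_idx] == pytest.approx(0.2)
        assert ens.mean_ratio[zero_idx - 1] == pytest.approx(0.9)

    def test_shift_equivariance(self):
        base = np.full(60, 0.9)
        base[30:] = 0.2
        t1 = Trace.from_series(base)
        t2 = Trace.from_series(base, start_frame=13)
        e1 = align_traces([t1], "ratio_half_drop")
        e2 = align_traces([t2], "ratio_half_drop")
        assert np.array_equal(e1.rel_frames, e2.rel_frames)
        assert np.allclose(e1.mean_ratio, e2.mean_ratio, equal_nan=True)

    def test_trace_without_anchor_excluded(self):
        flat = Trace.from_series(np.full(40, 0.9))
        good = _sigmoid_trace()
        ens = align_traces([flat, good], "ratio_half_drop")
        assert len(ens.excluded) == 1 and ens.excluded[0][0] == 0


class TestProgress:
    def test_boundary_values(self):
        ratio = np.full(40, 0.9)
        ratio[20:] = 0.2
        trace = Trace.from_series(ratio)
        assert ratio_progress_at_event(trace, 10) == pytest.approx(0.0)
        assert ratio_progress_at_event(trace, 30) == pytest.approx(1.0)

    def test_affine_invariance(self):
        trace1 = _sigmoid_trace()
        trace2 = Trace.from_series(0.5 * trace1.ratio + 0.2)
        for f in (28, 33, 38):
            assert ratio_progress_at_event(trace1, f) == pytest.approx(
                ratio_progress_at_event(trace2, f), abs=1e-9
            )

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            ratio_progress_at_event(Trace.from_series(np.full(40, 0.9)), 20)


def _scripted_track(n_frames=80, switch=40, seed=0, d_coeff=0.5):
    ms = MotionScript.single_switch(n_frames, switch, d_coeff, 0.5)
    pos = simulate_positions(ms, (50.0, 50.0), n_frames, seed=seed)
    dets = {
        f: ParticleDetection(frame=f, x=pos[f, 0], y=pos[f, 1], radius=4.0)
        for f in range(n_frames)
    }
    return Track(track_id=0, detections=dets)


class TestMobility:
    def test_switch_increases_median_displacement(self):
        track = _scripted_track(seed=1)
        ep = MarkerEpisode("stx17", 10, 39)
        phases = mobility_by_phase(track, ep)
        assert phases.median("after") > phases.median("during")

    def test_uniform_motion_null_case(self):
        track = _scripted_track(switch=0, seed=2)  # diffusive throughout
        ep = MarkerEpisode("stx17", 20, 50)
        phases = mobility_by_phase(track, ep)
        meds = [phases.median(p) for p in ("before", "during", "after")]
        assert max(meds) / min(meds) < 3.0

    def test_episode_covering_track_leaves_no_flanks(self):
        track = _scripted_track(seed=3)
        ep = MarkerEpisode("stx17", 0, 79)
        phases = mobility_by_phase(track, ep)
        assert len(phases.before) == 0 and len(phases.after) == 0
        assert phases.median("before") is None

    def test_switch_estimator_near_truth(self):
        errs = []
        for seed in range(20):
            track = _scripted_track(seed=100 + seed)
            est = estimate_mobility_switch(frame_displacements(track))
            errs.append(est - 40)
        assert abs(np.median(errs)) <= 1


class TestRab7Ensemble:
    def _traces(self, n=6):
        traces = []
        for i in range(n):
            ratio = simulate_acidification_trace(25, 10, 70)
            marker = simulate_marker_trace("rab7", (20, 60), 70, seed=i,
                                           rab7_event_rate=0.3)
            traces.append(Trace.from_series(ratio, marker))
        return traces

    def test_gradualness_flags_all_true(self):
        _, flags = rab7_accumulation_ensemble(self._traces())
        assert len(flags) == 6 and all(flags)

    def test_mean_marker_rises_toward_anchor(self):
        ens, _ = rab7_accumulation_ensemble(self._traces())
        zero_idx = int(np.argmax(ens.rel_frames == 0))
        first = int(np.argmax(ens.n > 0))
        assert ens.mean_marker[zero_idx] > ens.mean_marker[first]

    def test_single_trace_degenerate(self):
        (trace,) = self._traces(1)
        ens, flags = rab7_accumulation_ensemble([trace])
        full = ens.n == 1
        assert np.all(ens.sd_marker[full] < 1e-12)
        assert flags == [True]
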