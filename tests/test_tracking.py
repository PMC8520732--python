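"""Linking, trace extraction, and displacement series."""

import numpy as np
import pytest

from aggrephagy.detection import ParticleDetection
from aggrephagy.pipeline import track_movie
from aggrephagy.scoring import track_identity_agreement
from aggrephagy.sim import NOISELESS, FieldConfig, simulate_field
from aggrephagy.tracking import Track, frame_displacements, link_detections


def _det(frame, x, y):
    return ParticleDetection(frame=frame, x=x, y=y, radius=4.0)


class TestLinking:
    def test_stationary_spot_single_track(self):
        dets = [_det(f, 10.0, 10.0) for f in range(10)]
        tracks = link_detections(dets)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(10))

    def test_crossing_spots_keep_identity(self):
        # two spots cross in x but stay in lanes separated by more than
        # max_disp, so swapping identities would need a forbidden jump
        dets = []
        for f in range(11):
            dets.append(_det(f, 10.0 + 2.0 * f, 10.0))
            dets.append(_det(f, 30.0 - 2.0 * f, 18.0))
        tracks = link_detections(dets, max_disp=5.0)
        assert len(tracks) == 2
        for t in tracks:
            ys = {t.position(f)[1] for f in t.frames}
            assert len(ys) == 1  # never hopped lanes

    def test_gap_bridged_and_flagged(self):
        dets = [_det(f, 10.0, 10.0) for f in (0, 1, 2, 4, 5)]
        tracks = link_detections(dets, max_gap=2)
        assert len(tracks) == 1
        assert tracks[0].gap_frames == {3}
        assert tracks[0].frames == [0, 1, 2, 3, 4, 5]

    def test_gap_beyond_limit_splits_track(self):
        dets = [_det(f, 10.0, 10.0) for f in (0, 1, 2, 7, 8)]
        tracks = link_detections(dets, max_gap=2)
        assert len(tracks) == 2

    def test_permutation_invariance_within_frame(self):
        rng = np.random.default_rng(0)
        dets = []
        for f in range(8):
            for k in range(4):
                dets.append(_det(f, 10.0 + 12.0 * k + 0.2 * f, 10.0 + 10.0 * k))
        shuffled = dets.copy()
        rng.shuffle(shuffled)
        t1 = link_detections(dets)
        t2 = link_detections(shuffled)
        sets1 = sorted(tuple(sorted((f, round(t.position(f)[0], 6)) for f in t.frames)) for t in t1)
        sets2 = sorted(tuple(sorted((f, round(t.position(f)[0], 6)) for f in t.frames)) for t in t2)
        assert sets1 == sets2

    def test_identity_agreement_on_simulated_field(self):
        cfg = FieldConfig(
            scenario="control_8h", n_aggregates=5, n_frames=60, shape_yx=(256, 256),
            p_acidified=1.0, markers=("stx17",), min_separation=30.0,
        )
        stack, truth = simulate_field(cfg, seed=11)
        _, tracks, _ = track_movie(stack)
        assert len(tracks) == 5
        assert track_identity_agreement(tracks, truth) >= 0.99


class TestTraces:
    def test_noiseless_trace_matches_scripted_ratio(self):
        cfg = FieldConfig(
            scenario="control_8h", n_aggregates=1, n_frames=40, shape_yx=(64, 64),
            p_acidified=1.0, noise=NOISELESS,
        )
        stack, truth = simulate_field(cfg, seed=3)
        _, tracks, traces = track_movie(stack)
        assert len(traces) == 1
        tr = traces[0]
        true_r = truth.true_ratio[0][tr.frames]
        ok = tr.valid()
        assert np.all(np.abs(tr.ratio[ok] - true_r[ok]) < 0.02)

    def test_absent_marker_stays_near_zero(self):
        cfg = FieldConfig(
            scenario="control_8h", n_aggregates=1, n_frames=20, shape_yx=(64, 64),
            p_acidified=0.0,
        )
        stack, _ = simulate_field(cfg, seed=4)
        _, _, traces = track_movie(stack)
        marker = traces[0].marker_raw[traces[0].valid()]
        # no marker rendered: background-subtracted signal fluctuates
        # around zero within shot-noise scale of the integration window
        assert np.abs(np.nanmean(marker)) < 50.0

    def test_ratio_invariant_under_global_scaling(self):
        cfg = FieldConfig(
            scenario="control_8h", n_aggregates=1, n_frames=10, shape_yx=(64, 64),
            p_acidified=0.0, noise=NOISELESS,
        )
        stack, _ = simulate_field(cfg, seed=5)
        _, _, traces1 = track_movie(stack)
        stack2 = stack.with_pixels(stack.pixels * 2.5)
        _, _, traces2 = track_movie(stack2)
        ok = traces1[0].valid() & traces2[0].valid()
        assert np.allclose(traces1[0].ratio[ok], traces2[0].ratio[ok], atol=1e-9)


class TestDisplacements:
    def test_stationary_track_all_zero(self):
        t = Track(0, {f: _det(f, 5.0, 5.0) for f in range(6)})
        assert np.allclose(frame_displacements(t).values, 0.0)

    def test_uniform_motion_arithmetic(self):
        t = Track(0, {f: _det(f, 5.0 + f, 5.0) for f in range(6)})
        d = frame_displacements(t, pixel_size=0.1)
        assert np.allclose(d.values, 0.1)

    def test_gap_intervals_excluded(self):
        t = Track(0, {f: _det(f, float(f), 0.0) for f in range(6)})
        t.gap_frames = {3}
        d = frame_displacements(t)
        assert 2 not in d.index and 3 not in d.index
        assert len(d) == 3

    def test_singleton_track_empty(self):
        t = Track(0, {0: _det(0, 1.0, 1.0)})
        assert len(frame_displacements(t)) == 0
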