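"""Cohort-scale validation experiments.

Each function simulates a cohort under the study conditions, runs the full
measurement pipeline on the rendered data, scores the result against the
simulator's scripted truth, and returns a flat dict of metrics.  They are
what the acceptance checks and the analysis drivers both run; everything is
deterministic in the passed seed.
"""

from __future__ import annotations

import numpy as np

from .detection import ParticleDetection, detect_stack, detections_to_frame
from .events import (
    dfcp1_acidification_interval,
    estimate_mobility_switch,
    mobility_by_phase,
    ratio_progress_at_event,
    score_marker_presence,
)
from .facs import Gate, gate_positive, roi_fraction
from .pipeline import track_movie
from .ratiometry import clearance_summary, records_from_detections
from .scoring import detection_scores, match_points
from .sim import (
    NOISELESS,
    FieldConfig,
    MotionScript,
    simulate_facs_population,
    simulate_field,
    simulate_positions,
)
from .sim.spectral import acidification_progress
from .tracking import Track, frame_displacements

__all__ = [
    "detection_benchmark",
    "ratio_fidelity",
    "clearance_recovery",
    "timing_benchmark",
    "mobility_benchmark",
    "facs_benchmark",
]


def _seed(base: int, i: int) -> int:
    return int((base * 9973 + i) % (2**31))


# -- detection ---------------------------------------------------------------


def detection_benchmark(
    seed: int = 0, n_fields: int = 20, n_spots: int = 10
) -> dict[str, float]:
    """Detection oracle: recall/precision/centroid RMSE on noiseless
    well-separated fields, plus recall at default noise and SNR 8."""
    stats_clean, stats_noisy = [], []
    for i in range(n_fields):
        base = dict(
            n_aggregates=n_spots, n_frames=1, shape_yx=(160, 160),
            p_acidified=0.5, min_separation=10.0,
        )
        for noisy, bucket in ((False, stats_clean), (True, stats_noisy)):
            cfg = FieldConfig(**base) if noisy else FieldConfig(**base, noise=NOISELESS)
            stack, truth = simulate_field(cfg, _seed(seed, i))
            df = detections_to_frame(detect_stack(stack))
            true_xy = np.array([pos[0] for pos in truth.positions])
            bucket.append(detection_scores(df[["x", "y"]].to_numpy(), true_xy))
    return {
        "recall_noiseless": float(np.mean([s["recall"] for s in stats_clean])),
        "precision_noiseless": float(np.mean([s["precision"] for s in stats_clean])),
        "centroid_rmse_noiseless_px": float(
            np.sqrt(np.mean([s["rmse"] ** 2 for s in stats_clean]))
        ),
        "recall_noisy": float(np.mean([s["recall"] for s in stats_noisy])),
        "centroid_rmse_noisy_px": float(
            np.sqrt(np.mean([s["rmse"] ** 2 for s in stats_noisy]))
        ),
    }


# -- ratiometry --------------------------------------------------------------


def _ratio_errors(cfg: FieldConfig, seed: int) -> np.ndarray:
    stack, truth = simulate_field(cfg, seed)
    df = detections_to_frame(detect_stack(stack))
    true_xy = np.array([pos[0] for pos in truth.positions])
    pairs = match_points(df[["x", "y"]].to_numpy(), true_xy, 2.0)
    errs = []
    for ci, ri in pairs:
        total = df.i445[ci] + df.i561[ci]
        if total <= 0 or "border" in str(df["flags"][ci]):
            continue
        errs.append(df.i445[ci] / total - truth.true_ratio[ri][0])
    return np.asarray(errs)


def ratio_fidelity(seed: int = 0, n_particles: int = 500) -> dict[str, float]:
    """End-to-end measured ratio vs scripted truth, noiseless and noisy."""
    per_field = 100
    n_fields = int(np.ceil(n_particles / per_field))
    errs_clean, errs_noisy = [], []
    for i in range(n_fields):
        base = dict(
            n_aggregates=per_field, n_frames=1, shape_yx=(480, 480),
            p_acidified=0.5, min_separation=10.0,
        )
        errs_clean.append(_ratio_errors(FieldConfig(**base, noise=NOISELESS), _seed(seed, i)))
        errs_noisy.append(_ratio_errors(FieldConfig(**base), _seed(seed, 1000 + i)))
    clean = np.concatenate(errs_clean)
    noisy = np.concatenate(errs_noisy)
    return {
        "ratio_rms_noiseless": float(np.sqrt(np.mean(clean**2))),
        "ratio_rms_noisy": float(np.sqrt(np.mean(noisy**2))),
        "n_particles_noiseless": int(clean.size),
        "n_particles_noisy": int(noisy.size),
    }


# -- clearance ---------------------------------------------------------------


def _pipeline_cleared_fraction(cfg: FieldConfig, seed: int, n_reps: int) -> float:
    by_rep = {}
    for rep in range(n_reps):
        stack, _ = simulate_field(cfg, _seed(seed, rep))
        df = detections_to_frame(detect_stack(stack))
        by_rep[f"rep{rep}"] = records_from_detections(df, f"rep{rep}", cfg.scenario)
    return clearance_summary(by_rep).mean


def clearance_recovery(
    seed: int = 0,
    p_values: tuple[float, ...] = (0.1, 0.4, 0.7),
    n_reps: int = 3,
    n_particles: int = 500,
    n_seeds: int = 10,
) -> dict[str, float]:
    """Cleared-fraction recovery across scripted acidified probabilities,
    plus the false-positive floor of the blocked (Bafilomycin) scenario."""
    out: dict[str, float] = {}
    for p in p_values:
        cfg = FieldConfig(
            scenario="control_8h", n_aggregates=n_particles, n_frames=1,
            shape_yx=(640, 640), p_acidified=p, min_separation=8.0,
        )
        means = [
            _pipeline_cleared_fraction(cfg, _seed(seed, 77 + s), n_reps)
            for s in range(n_seeds)
        ]
        key = f"cleared_fraction_p{int(round(100 * p)):02d}"
        out[key] = float(np.mean(means))
        out[key + "_maxdev"] = float(np.max(np.abs(np.array(means) - p)))
    baf = FieldConfig(
        scenario="bafilomycin", n_aggregates=n_particles, n_frames=1,
        shape_yx=(640, 640), min_separation=8.0,
    )
    out["bafilomycin_cleared_fraction"] = float(np.mean([
        _pipeline_cleared_fraction(baf, _seed(seed, 7700 + s), n_reps)
        for s in range(max(1, n_seeds // 3))
    ]))
    return out


# -- event timing ------------------------------------------------------------


def _stx17_movie() -> FieldConfig:
    return FieldConfig(
        scenario="control_8h", n_aggregates=1, n_frames=60, shape_yx=(64, 64),
        p_acidified=1.0, markers=("stx17",),
    )


def timing_benchmark(seed: int = 0, n_events: int = 50) -> dict[str, float]:
    """Recover scripted STX17 dwell, acidification progress at STX17
    release, DFCP1->acidification intervals, and alignment anchors from
    rendered movies at default noise."""
    dwell_frames, progress_meas, progress_truth, progress_tol = [], [], [], []
    half_drop_err = []
    for i in range(n_events):
        cfg = _stx17_movie()
        stack, truth = simulate_field(cfg, _seed(seed, i))
        script = truth.scripts[0]
        _, tracks, traces = track_movie(stack)
        if not traces:
            continue
        trace = max(traces, key=lambda tr: len(tr.frames))
        eps = score_marker_presence(
            np.nan_to_num(trace.marker_norm), marker="stx17", frames=trace.frames
        )
        if not eps:
            continue
        ep = max(eps, key=lambda e: e.n_frames)
        dwell_frames.append(ep.n_frames)
        release = ep.end_frame + 1
        progress_meas.append(ratio_progress_at_event(trace, release))
        progress_truth.append(script.progress_at_stx17_release)
        # one-frame discretization band around the scripted release
        o, d = script.acidification_onset, script.acidification_duration
        p0 = acidification_progress(o, d, script.stx17_release_frame)
        pm = acidification_progress(o, d, script.stx17_release_frame - 1)
        pp = acidification_progress(o, d, script.stx17_release_frame + 1)
        progress_tol.append(max(abs(pp - p0), abs(p0 - pm)))
        # half-drop anchor vs scripted
        from .events import anchor_frame

        a = anchor_frame(trace, "ratio_half_drop")
        if a is not None and script.half_drop_frame is not None:
            half_drop_err.append(a - script.half_drop_frame)

    interval_err_frames: list[float] = []
    interval_meas_min: list[float] = []
    for i in range(n_events):
        cfg = FieldConfig(
            scenario="control_8h", n_aggregates=1, n_frames=110, shape_yx=(64, 64),
            p_acidified=1.0, markers=("dfcp1",),
        )
        stack, truth = simulate_field(cfg, _seed(seed, 5000 + i))
        script = truth.scripts[0]
        _, tracks, traces = track_movie(stack)
        if not traces:
            continue
        trace = max(traces, key=lambda tr: len(tr.frames))
        res = dfcp1_acidification_interval(trace)
        if not res.valid:
            continue
        truth_frames = script.acid_crossing_frame - script.dfcp1_release_frame
        meas_frames = res.minutes * 60.0 / 20.0
        interval_err_frames.append(meas_frames - truth_frames)
        interval_meas_min.append(res.minutes)

    dwell = np.asarray(dwell_frames, dtype=float)
    ierr = np.asarray(interval_err_frames, dtype=float)
    pmeas = np.asarray(progress_meas, dtype=float)
    ptruth = np.asarray(progress_truth, dtype=float)
    ptol = np.asarray(progress_tol, dtype=float)
    return {
        "stx17_dwell_mean_min": float(dwell.mean() * 20.0 / 60.0),
        "stx17_dwell_mean_frames": float(dwell.mean()),
        "stx17_dwell_n": int(dwell.size),
        "dfcp1_interval_max_abs_err_frames": float(np.max(np.abs(ierr))),
        "dfcp1_interval_mean_abs_err_frames": float(np.mean(np.abs(ierr))),
        "dfcp1_interval_mean_min": float(np.mean(interval_meas_min)),
        "dfcp1_interval_n": int(ierr.size),
        "progress_at_stx17_release_mean": float(pmeas.mean()),
        "progress_max_abs_dev_from_scripted": float(np.max(np.abs(pmeas - ptruth))),
        "progress_n_within_discretization": int(
            np.sum(np.abs(pmeas - 0.30) <= ptol + 0.05)
        ),
        "progress_n": int(pmeas.size),
        "half_drop_anchor_max_abs_err_frames": float(
            np.max(np.abs(half_drop_err)) if half_drop_err else np.nan
        ),
    }


# -- mobility ----------------------------------------------------------------


def mobility_benchmark(
    seed: int = 0,
    n_tracks: int = 100,
    n_frames: int = 80,
    switch_frame: int = 40,
    diffusion_coeff: float = 0.5,
) -> dict[str, float]:
    """Phase-resolved mobility on scripted confined -> diffusive tracks:
    median ordering, switch change-point recovery, diffusive-phase MSD."""
    from .events import MarkerEpisode

    ordered = 0
    switch_err = []
    sq_disp_diffusive = []
    for i in range(n_tracks):
        ms = MotionScript.single_switch(n_frames, switch_frame, diffusion_coeff, 0.5)
        pos = simulate_positions(ms, (50.0, 50.0), n_frames, _seed(seed, i))
        dets = {
            f: ParticleDetection(frame=f, x=pos[f, 0], y=pos[f, 1], radius=4.0)
            for f in range(n_frames)
        }
        track = Track(track_id=i, detections=dets)
        # marker episode mirrors the tether: present until the switch
        ep = MarkerEpisode("stx17", 10, switch_frame - 1)
        phases = mobility_by_phase(track, ep)
        m_during, m_after = phases.median("during"), phases.median("after")
        if m_during is not None and m_after is not None and m_after > m_during:
            ordered += 1
        est = estimate_mobility_switch(frame_displacements(track))
        if est is not None:
            switch_err.append(est - switch_frame)
        sq_disp_diffusive.extend(phases.after**2)

    msd_lag1 = float(np.mean(sq_disp_diffusive))
    err = np.asarray(switch_err, dtype=float)
    return {
        "fraction_after_gt_during": ordered / n_tracks,
        "switch_err_median_frames": float(np.median(err)),
        "switch_within_2_frames_fraction": float(np.mean(np.abs(err) <= 2)),
        "msd_lag1_over_4d": msd_lag1 / (4.0 * diffusion_coeff),
        "n_tracks": n_tracks,
    }


# -- FACS --------------------------------------------------------------------

#: ROI capturing the acidified (shifted) component; the default synthetic
#: components are >= 1 decade apart along log10 i_low, so the boundary at
#: 2.6 sits in the trough between them.
ROI1 = Gate("roi1", "polygon", {"vertices": [(0.0, 2.6), (6.0, 2.6), (6.0, 8.0), (0.0, 8.0)]})


def facs_benchmark(
    seed: int = 0,
    fractions: tuple[float, ...] = (0.01, 0.2),
    n_cells: int = 20000,
    n_seeds: int = 10,
) -> dict[str, float]:
    """Recover scripted shifted fractions from gated mixtures."""
    out: dict[str, float] = {}
    for f in fractions:
        rec = []
        for s in range(n_seeds):
            events = gate_positive(
                simulate_facs_population(n_cells, f, _seed(seed, s)), min_total=10.0
            )
            rec.append(roi_fraction(events, ROI1))
        key = f"facs_roi1_pct_f{int(round(100 * f)):02d}"
        out[key] = float(np.mean(rec))
        out[key + "_maxdev_pp"] = float(np.max(np.abs(np.array(rec) - 100.0 * f)))
    return out
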