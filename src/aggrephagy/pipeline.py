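"""End-to-end convenience flows: stack -> detections -> tracks -> traces."""

from __future__ import annotations

import pandas as pd

from .detection import (
    DetectionParams,
    ParticleDetection,
    default_cell_mask,
    detect_stack,
)
from .stack import ImageStack
from .tracking import Trace, Track, extract_trace, link_detections

__all__ = ["track_movie", "traces_to_frame", "traces_from_frame"]


def track_movie(
    stack: ImageStack,
    params: DetectionParams = DetectionParams(),
    max_disp: float = 5.0,
    max_gap: int = 2,
    min_track_length: int = 3,
) -> tuple[list[ParticleDetection], list[Track], list[Trace]]:
    """Detect, link, and extract traces for a whole time-lapse.

    The cell mask is computed once on the first frame and reused (the
    simulated cell does not move); short spurious tracks are dropped.
    """
    mask = default_cell_mask(stack, 0)
    detections = detect_stack(stack, params, cell_mask=mask)
    tracks = [
        t for t in link_detections(detections, max_disp=max_disp, max_gap=max_gap)
        if len(t.frames) >= min_track_length
    ]
    traces = [
        extract_trace(t, stack, params, all_detections=detections, cell_mask=mask)
        for t in tracks
    ]
    return detections, tracks, traces


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """All traces as one tidy table (one row per track per frame)."""
    rows = []
    for trace in traces:
        for k, f in enumerate(trace.frames):
            x, y = trace.track.position(f)
            rows.append({
                "track_id": trace.track.track_id,
                "frame": int(f),
                "t_s": float(trace.t[k]),
                "x": x,
                "y": y,
                "ratio": trace.ratio[k],
                "marker_raw": trace.marker_raw[k],
                "marker_norm": trace.marker_norm[k],
                "interpolated": bool(trace.interpolated[k]),
                "missing": bool(trace.missing[k]),
            })
    return pd.DataFrame(rows)


def traces_from_frame(df: pd.DataFrame, frame_interval: float = 20.0) -> list[Trace]:
    """Rebuild Trace objects from a traces table (inverse of
    :func:`traces_to_frame`)."""
    traces = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        dets = {}
        gaps = set()
        for _, row in g.iterrows():
            f = int(row["frame"])
            d = ParticleDetection(frame=f, x=float(row["x"]), y=float(row["y"]), radius=4.0)
            dets[f] = d
            if bool(row["interpolated"]):
                gaps.add(f)
        track = Track(track_id=int(tid), detections=dets, gap_frames=gaps)
        traces.append(Trace(
            track=track,
            t=g["t_s"].to_numpy(float),
            frames=g["frame"].to_numpy(int),
            ratio=g["ratio"].to_numpy(float),
            marker_raw=g["marker_raw"].to_numpy(float),
            marker_norm=g["marker_norm"].to_numpy(float),
            interpolated=g["interpolated"].to_numpy(bool),
            missing=g["missing"].to_numpy(bool),
        ))
    return traces
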