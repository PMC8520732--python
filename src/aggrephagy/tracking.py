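"""Linking detections into tracks and extracting per-particle traces.

The original single-particle analysis tracked aggregates manually; here
linking is automated as a per-frame linear assignment problem (minimum
summed squared displacement, links beyond ``max_disp`` rejected), with
tracks allowed to bridge up to ``max_gap`` missing frames by linear
interpolation.  A trace is the background-subtracted ratio and GFP-marker
intensity of one track over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import (
    DetectionParams,
    ParticleDetection,
    default_cell_mask,
    disc_sum,
    estimate_background,
)
from .stack import ImageStack

__all__ = ["Track", "Trace", "link_detections", "extract_trace", "frame_displacements"]

_FORBIDDEN = 1e12


@dataclass
class Track:
    """Linked detections over frames; ``gap_frames`` were interpolated."""

    track_id: int
    detections: dict[int, ParticleDetection] = field(default_factory=dict)
    gap_frames: set[int] = field(default_factory=set)

    @property
    def frames(self) -> list[int]:
        return sorted(self.detections)

    @property
    def start(self) -> int:
        return min(self.detections)

    @property
    def end(self) -> int:
        return max(self.detections)

    def position(self, frame: int) -> tuple[float, float]:
        d = self.detections[frame]
        return d.x, d.y

    def positions(self) -> np.ndarray:
        """(n, 2) xy over the track's frames (including interpolated)."""
        return np.array([self.position(f) for f in self.frames])


def _group_by_frame(detections: list[ParticleDetection]) -> dict[int, list[ParticleDetection]]:
    by_frame: dict[int, list[ParticleDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    return by_frame


def link_detections(
    detections: list[ParticleDetection],
    max_disp: float = 5.0,
    max_gap: int = 2,
) -> list[Track]:
    """Link detections into tracks.

    For every frame, open tracks (last seen within ``max_gap + 1`` frames)
    compete for the frame's detections in a linear assignment minimizing
    summed squared displacement; candidate links further than
    ``max_disp`` px per elapsed frame are forbidden.  Unmatched detections
    seed new tracks; bridged frames get linearly interpolated positions
    flagged as gaps.  Ties are resolved deterministically (lower track id
    first).
    """
    by_frame = _group_by_frame(detections)
    if not by_frame:
        return []
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    for f in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(f, [])
        open_tracks = [t for t in open_tracks if f - t.end <= max_gap + 1]
        open_tracks.sort(key=lambda t: t.track_id)
        assigned_det: set[int] = set()
        if open_tracks and dets:
            cost = np.full((len(open_tracks), len(dets)), _FORBIDDEN)
            for i, t in enumerate(open_tracks):
                tx, ty = t.position(t.end)
                elapsed = f - t.end
                budget = max_disp * elapsed
                for j, d in enumerate(dets):
                    dist2 = (d.x - tx) ** 2 + (d.y - ty) ** 2
                    if dist2 <= budget**2:
                        cost[i, j] = dist2
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= _FORBIDDEN:
                    continue
                t = open_tracks[i]
                _bridge_gap(t, f, dets[j])
                t.detections[f] = dets[j]
                assigned_det.add(j)
        for j, d in enumerate(dets):
            if j not in assigned_det:
                t = Track(track_id=next_id, detections={f: d})
                next_id += 1
                tracks.append(t)
                open_tracks.append(t)
    return tracks


def _bridge_gap(track: Track, frame: int, det: ParticleDetection) -> None:
    """Insert linearly interpolated detections across a bridged gap."""
    last = track.end
    if frame - last <= 1:
        return
    x0, y0 = track.position(last)
    for g in range(last + 1, frame):
        w = (g - last) / (frame - last)
        gx = x0 + w * (det.x - x0)
        gy = y0 + w * (det.y - y0)
        ghost = ParticleDetection(frame=g, x=gx, y=gy, radius=det.radius)
        ghost.flags.add("interpolated")
        track.detections[g] = ghost
        track.gap_frames.add(g)


@dataclass
class Trace:
    """Per-frame measurements along one track.

    ``ratio`` and ``marker_raw`` are NaN at missing points (border-clipped
    windows); ``interpolated`` marks bridged gap frames, which contribute
    to the series but are ignored when anchoring events.
    """

    track: Track
    t: np.ndarray  # seconds
    frames: np.ndarray
    ratio: np.ndarray
    marker_raw: np.ndarray
    marker_norm: np.ndarray
    interpolated: np.ndarray  # bool
    missing: np.ndarray  # bool

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 20.0

    def valid(self) -> np.ndarray:
        return ~self.missing

    @classmethod
    def from_series(
        cls,
        ratio,
        marker=None,
        frame_interval: float = 20.0,
        positions: np.ndarray | None = None,
        track_id: int = 0,
        start_frame: int = 0,
        missing: np.ndarray | None = None,
    ) -> "Trace":
        """Build a trace directly from measured series.

        Convenient for externally measured data and for constructing
        synthetic traces; positions default to a stationary particle.
        """
        ratio = np.asarray(ratio, dtype=float)
        n = len(ratio)
        marker = np.zeros(n) if marker is None else np.asarray(marker, dtype=float)
        if positions is None:
            positions = np.zeros((n, 2))
        frames = np.arange(start_frame, start_frame + n)
        dets = {
            int(f): ParticleDetection(frame=int(f), x=float(positions[k, 0]),
                                      y=float(positions[k, 1]), radius=4.0)
            for k, f in enumerate(frames)
        }
        peak = marker.max() if marker.size and marker.max() > 0 else 1.0
        return cls(
            track=Track(track_id=track_id, detections=dets),
            t=frames * frame_interval,
            frames=frames,
            ratio=ratio,
            marker_raw=marker,
            marker_norm=marker / peak,
            interpolated=np.zeros(n, dtype=bool),
            missing=np.zeros(n, dtype=bool) if missing is None else np.asarray(missing, dtype=bool),
        )


def extract_trace(
    track: Track,
    stack: ImageStack,
    params: DetectionParams = DetectionParams(),
    all_detections: list[ParticleDetection] | None = None,
    cell_mask: np.ndarray | None = None,
) -> Trace:
    """Measure all three channels along a track and form its trace.

    Backgrounds are estimated per frame per channel as the median of
    in-cell pixels away from every detection (all detections of the frame
    when provided, else the track's own position).  The marker series is
    also returned max-normalized for event scoring.
    """
    ex445 = stack.channel("mkeima_ex445")
    ex561 = stack.channel("mkeima_ex561")
    gfp = stack.channel("gfp_marker")
    by_frame = _group_by_frame(all_detections) if all_detections else None

    frames = np.array(track.frames)
    n = len(frames)
    ratio = np.full(n, np.nan)
    marker = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    interp = np.array([f in track.gap_frames for f in frames])

    for k, f in enumerate(frames):
        x, y = track.position(f)
        mask = cell_mask if cell_mask is not None else default_cell_mask(stack, f)
        excl = by_frame.get(f, [track.detections[f]]) if by_frame else [track.detections[f]]
        bg445 = estimate_background(ex445[f], excl, mask, params.particle_size)
        bg561 = estimate_background(ex561[f], excl, mask, params.particle_size)
        bggfp = estimate_background(gfp[f], excl, mask, params.particle_size)
        s445, area, c1 = disc_sum(ex445[f], x, y, params.r_int)
        s561, _, c2 = disc_sum(ex561[f], x, y, params.r_int)
        sgfp, _, c3 = disc_sum(gfp[f], x, y, params.r_int)
        if c1 or c2 or c3:
            missing[k] = True
            continue
        i445 = max(0.0, s445 - area * bg445)
        i561 = max(0.0, s561 - area * bg561)
        marker[k] = sgfp - area * bggfp
        if i445 + i561 > 0:
            ratio[k] = i445 / (i445 + i561)
        else:
            missing[k] = True

    finite = marker[~np.isnan(marker)]
    peak = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    return Trace(
        track=track,
        t=frames * stack.frame_interval,
        frames=frames,
        ratio=ratio,
        marker_raw=marker,
        marker_norm=marker / peak,
        interpolated=interp,
        missing=missing,
    )


def frame_displacements(track: Track, pixel_size: float = 1.0) -> pd.Series:
    """Per-interval displacements (um per frame interval).

    Only consecutive-frame intervals between measured (non-interpolated)
    positions contribute; the series is indexed by the interval's first
    frame.  A length-1 track yields an empty series.
    """
    frames = track.frames
    disp, idx = [], []
    for f0, f1 in zip(frames[:-1], frames[1:]):
        if f1 - f0 != 1:
            continue
        if f0 in track.gap_frames or f1 in track.gap_frames:
            continue
        x0, y0 = track.position(f0)
        x1, y1 = track.position(f1)
        disp.append(np.hypot(x1 - x0, y1 - y0) * pixel_size)
        idx.append(f0)
    return pd.Series(disp, index=pd.Index(idx, name="frame"), dtype=float, name="displacement")
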