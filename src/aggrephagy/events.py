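"""Event-timing analysis of marker recruitment and acidification.

Computations:

* marker-presence scoring with hysteresis (replaces manual scoring of
  STX17/DFCP1/RAB7 presence at an aggregate);
* the DFCP1 -> acidification interval: time between the normalized DFCP1
  signal dropping and staying below 0.7 of its maximum and the mKeima
  ratio dropping and staying below 0.8;
* STX17 dwell time (episode length in minutes);
* trace alignment on either the first frame after STX17 disappearance or
  the frame at which the ratio has dropped halfway to its minimum, with
  ensemble mean +/- s.d. per relative frame;
* acidification progress at an event frame (fraction of total ratio
  change);
* phase-resolved mobility (before / during / after a marker episode) and
  a variance change-point estimator for the confined -> mobile switch;
* RAB7 accumulation ensembles with a per-trace gradualness flag.

"Dropped and stayed below" is read strictly: below the threshold at every
subsequent non-missing point of the trace.  Frames flagged missing (out of
focus, border-clipped, overlapped) are excluded from anchor location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import Trace, Track, frame_displacements

__all__ = [
    "MarkerEpisode",
    "AlignedEnsemble",
    "IntervalResult",
    "MobilityPhases",
    "score_marker_presence",
    "dfcp1_acidification_interval",
    "stx17_dwell_time",
    "align_traces",
    "ratio_progress_at_event",
    "mobility_by_phase",
    "estimate_mobility_switch",
    "rab7_accumulation_ensemble",
]


@dataclass(frozen=True)
class MarkerEpisode:
    """Contiguous marker presence at an aggregate (inclusive frames)."""

    marker: str
    start_frame: int
    end_frame: int
    on_frac: float = 0.5
    min_frames: int = 2
    track_id: int | None = None

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("episode start must not exceed end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def score_marker_presence(
    marker_norm: np.ndarray,
    on_frac: float = 0.5,
    min_frames: int = 2,
    off_margin: float = 0.1,
    marker: str = "marker",
    frames: np.ndarray | None = None,
) -> list[MarkerEpisode]:
    """Score maximal presence episodes on a max-normalized marker series.

    A frame is "on" at >= ``on_frac``.  Hysteresis: an episode only closes
    after two consecutive frames below ``on_frac - off_margin``, so
    single-frame dropouts are bridged.  Episodes shorter than
    ``min_frames`` are discarded.  ``frames`` maps series indices to frame
    numbers (defaults to 0..n-1).
    """
    v = np.asarray(marker_norm, dtype=float)
    frames = np.arange(len(v)) if frames is None else np.asarray(frames)
    off_thresh = on_frac - off_margin
    episodes: list[MarkerEpisode] = []
    in_episode = False
    start = end = 0
    below_off_run = 0
    for i, x in enumerate(v):
        if not in_episode:
            if x >= on_frac:
                in_episode, start, end = True, i, i
                below_off_run = 0
        else:
            if x >= on_frac:
                end = i
                below_off_run = 0
            else:
                if x < off_thresh:
                    below_off_run += 1
                else:
                    below_off_run = 0
                if below_off_run >= 2:
                    _close(episodes, marker, frames, start, end, on_frac, min_frames)
                    in_episode = False
    if in_episode:
        _close(episodes, marker, frames, start, end, on_frac, min_frames)
    return episodes


def _close(episodes, marker, frames, start, end, on_frac, min_frames) -> None:
    if end - start + 1 >= min_frames:
        episodes.append(MarkerEpisode(
            marker=marker,
            start_frame=int(frames[start]),
            end_frame=int(frames[end]),
            on_frac=on_frac,
            min_frames=min_frames,
        ))


def _stays_below_anchor(values: np.ndarray, frames: np.ndarray, threshold: float) -> int | None:
    """First frame at which ``values`` < threshold and remains below for
    every later point; None if it never settles below."""
    below = values < threshold
    if len(below) == 0 or not below[-1]:
        return None
    not_below = np.flatnonzero(~below)
    idx = int(not_below[-1] + 1) if len(not_below) else 0
    return int(frames[idx])


@dataclass(frozen=True)
class IntervalResult:
    """DFCP1 -> acidification interval for one trace.

    ``minutes`` is signed (negative if acidification precedes DFCP1
    release); ``reason`` is set when the event is excluded.
    """

    minutes: float | None
    t_dfcp1_frame: int | None
    t_acid_frame: int | None
    reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.reason is None


def dfcp1_acidification_interval(
    trace: Trace,
    dfcp1_frac: float = 0.7,
    ratio_thresh: float = 0.8,
) -> IntervalResult:
    """Interval between DFCP1 release and acidification onset, in minutes.

    DFCP1 release is the first time after the marker peak at which the
    max-normalized DFCP1 signal drops below ``dfcp1_frac`` and stays
    below; acidification onset is the first time the ratio drops below
    ``ratio_thresh`` and stays below.  Missing points are ignored.
    """
    ok = trace.valid() & ~np.isnan(trace.marker_norm) & ~np.isnan(trace.ratio)
    if ok.sum() < 3:
        return IntervalResult(None, None, None, "too_few_points")
    frames = trace.frames[ok]
    marker = trace.marker_norm[ok]
    marker = marker / marker.max() if marker.max() > 0 else marker
    ratio = trace.ratio[ok]

    peak = int(np.argmax(marker))
    t_dfcp1 = _stays_below_anchor(marker[peak:], frames[peak:], dfcp1_frac)
    if t_dfcp1 is None:
        return IntervalResult(None, None, None, "no_dfcp1_release")
    t_acid = _stays_below_anchor(ratio, frames, ratio_thresh)
    if t_acid is None:
        return IntervalResult(None, t_dfcp1, None, "no_acidification")
    minutes = (t_acid - t_dfcp1) * trace.frame_interval / 60.0
    return IntervalResult(float(minutes), t_dfcp1, t_acid)


def stx17_dwell_time(episode: MarkerEpisode, frame_interval: float = 20.0) -> float:
    """Episode duration in minutes: (end - start + 1) frames."""
    return episode.n_frames * frame_interval / 60.0


@dataclass
class AlignedEnsemble:
    """Traces aligned on a shared anchor (relative frame 0 = anchor).

    Mean and s.d. at each relative frame are computed only over traces
    contributing a valid point there; ``n`` records how many did.
    """

    anchor: str
    rel_frames: np.ndarray
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray
    mean_marker: np.ndarray
    sd_marker: np.ndarray
    n: np.ndarray
    anchor_frames: list[int]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "relative_frame": self.rel_frames,
            "mean_ratio": self.mean_ratio,
            "sd_ratio": self.sd_ratio,
            "mean_marker": self.mean_marker,
            "sd_marker": self.sd_marker,
            "n": self.n,
        })


def _half_drop_anchor(trace: Trace, r_start_frames: int = 5) -> int | None:
    """First valid frame at which the ratio has dropped halfway from its
    pre-event plateau (mean of the first ``r_start_frames`` valid points)
    to its minimum."""
    ok = trace.valid() & ~np.isnan(trace.ratio)
    frames = trace.frames[ok]
    ratio = trace.ratio[ok]
    if len(ratio) < max(3, r_start_frames):
        return None
    r_start = float(ratio[:r_start_frames].mean())
    r_min = float(ratio.min())
    if r_start <= r_min:
        return None
    half = (r_start + r_min) / 2.0
    hit = np.flatnonzero(ratio <= half)
    return int(frames[hit[0]]) if len(hit) else None


def anchor_frame(
    trace: Trace,
    anchor: str,
    episode: MarkerEpisode | None = None,
    r_start_frames: int = 5,
) -> int | None:
    """Anchor frame for one trace, or None if not computable."""
    if anchor == "stx17_disappearance":
        if episode is None:
            return None
        return episode.end_frame + 1
    if anchor == "ratio_half_drop":
        return _half_drop_anchor(trace, r_start_frames)
    raise ValueError(f"unknown anchor {anchor!r}")


def align_traces(
    traces: list[Trace],
    anchor: str,
    episodes: list[MarkerEpisode | None] | None = None,
    r_start_frames: int = 5,
) -> AlignedEnsemble:
    """Align traces on a common anchor and average per relative frame.

    ``anchor`` is ``stx17_disappearance`` (frame 0 = first frame after the
    episode) or ``ratio_half_drop`` (frame 0 = first frame at or below the
    half-way ratio).  Missing points never contribute; traces whose anchor
    cannot be computed are excluded with a reason.
    """
    if episodes is None:
        episodes = [None] * len(traces)
    aligned: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    anchors: list[int] = []
    excluded: list[tuple[int, str]] = []
    for i, (trace, ep) in enumerate(zip(traces, episodes)):
        a = anchor_frame(trace, anchor, ep, r_start_frames)
        if a is None:
            excluded.append((i, f"no_{anchor}_anchor"))
            continue
        ok = trace.valid()
        aligned.append((trace.frames[ok] - a, trace.ratio[ok], trace.marker_raw[ok]))
        anchors.append(a)
    if not aligned:
        raise ValueError("no trace had a computable anchor")

    lo = min(int(r.min()) for r, _, _ in aligned)
    hi = max(int(r.max()) for r, _, _ in aligned)
    rel = np.arange(lo, hi + 1)
    mat_r = np.full((len(aligned), len(rel)), np.nan)
    mat_m = np.full((len(aligned), len(rel)), np.nan)
    for k, (r, ratio, marker) in enumerate(aligned):
        idx = r.astype(int) - lo
        mat_r[k, idx] = ratio
        mat_m[k, idx] = marker
    counts = np.sum(~np.isnan(mat_r), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_r = np.nanmean(mat_r, axis=0)
        mean_m = np.nanmean(mat_m, axis=0)
        sd_r = np.nanstd(mat_r, axis=0)
        sd_m = np.nanstd(mat_m, axis=0)
    return AlignedEnsemble(
        anchor=anchor,
        rel_frames=rel,
        mean_ratio=mean_r,
        sd_ratio=sd_r,
        mean_marker=mean_m,
        sd_marker=sd_m,
        n=counts,
        anchor_frames=anchors,
        excluded=excluded,
    )


def ratio_progress_at_event(
    trace: Trace, event_frame: int, r_start_frames: int = 5
) -> float:
    """Fraction of the total ratio change completed at ``event_frame``.

    (r_start - r(event)) / (r_start - r_min), clamped to [0, 1], with
    r_start the pre-event plateau mean and r_min the trace minimum.
    """
    ok = trace.valid() & ~np.isnan(trace.ratio)
    frames = trace.frames[ok]
    ratio = trace.ratio[ok]
    if len(ratio) < max(3, r_start_frames):
        raise ValueError("trace too short for progress computation")
    r_start = float(ratio[:r_start_frames].mean())
    r_min = float(ratio.min())
    if r_start <= r_min:
        raise ValueError("flat trace: progress undefined")
    k = int(np.argmin(np.abs(frames - event_frame)))
    return float(np.clip((r_start - ratio[k]) / (r_start - r_min), 0.0, 1.0))


@dataclass
class MobilityPhases:
    """Frame-to-frame displacements split by marker-episode phase."""

    before: np.ndarray
    during: np.ndarray
    after: np.ndarray

    def median(self, phase: str) -> float | None:
        arr = getattr(self, phase)
        return float(np.median(arr)) if len(arr) else None

    def mean(self, phase: str) -> float | None:
        arr = getattr(self, phase)
        return float(np.mean(arr)) if len(arr) else None


def mobility_by_phase(
    track: Track,
    episode: MarkerEpisode,
    pixel_size: float = 1.0,
) -> MobilityPhases:
    """Partition a track's displacements into before/during/after phases.

    An interval (f, f+1) is "before" if it ends at or before the episode
    start, "after" if it begins at or after the episode end (the step out
    of the last marker-positive frame belongs to "after"), else "during".
    Empty phases come back as empty arrays.
    """
    disp = frame_displacements(track, pixel_size)
    before, during, after = [], [], []
    for f, d in disp.items():
        if f + 1 <= episode.start_frame:
            before.append(d)
        elif f >= episode.end_frame:
            after.append(d)
        else:
            during.append(d)
    return MobilityPhases(np.array(before), np.array(during), np.array(after))


def estimate_mobility_switch(displacements: pd.Series) -> int | None:
    """Estimate the confined -> mobile switch frame from a displacement
    series by a two-segment variance change-point fit.

    Squared displacements are modelled as exponential within each segment
    (2-D Gaussian steps); the split minimizing the summed log mean squared
    displacement is returned as the frame index of the first mobile
    position.  None for series too short to split.
    """
    s = np.asarray(displacements.values, dtype=float) ** 2
    n = len(s)
    if n < 4:
        return None
    eps = max(1e-12, s[s > 0].min() * 1e-6) if np.any(s > 0) else 1e-12
    best_k, best_ll = None, np.inf
    for k in range(2, n - 1):
        m1 = max(s[:k].mean(), eps)
        m2 = max(s[k:].mean(), eps)
        ll = k * np.log(m1) + (n - k) * np.log(m2)
        if ll < best_ll:
            best_ll, best_k = ll, k
    if best_k is None:
        return None
    # first interval of the mobile segment steps INTO the switch frame
    return int(displacements.index[best_k] + 1)


def rab7_accumulation_ensemble(
    traces: list[Trace],
    r_start_frames: int = 5,
    gradual_tol: float = 0.0,
) -> tuple[AlignedEnsemble, list[bool]]:
    """RAB7 + ratio joint ensemble aligned on the half-drop anchor.

    Also reports, per contributing trace, whether the marker series is
    non-decreasing (within ``gradual_tol`` of its running maximum) up to
    its peak -- the gradual, step-wise accumulation signature.
    """
    ensemble = align_traces(traces, "ratio_half_drop", r_start_frames=r_start_frames)
    excluded = {i for i, _ in ensemble.excluded}
    flags = []
    for i, trace in enumerate(traces):
        if i in excluded:
            continue
        ok = trace.valid() & ~np.isnan(trace.marker_raw)
        m = trace.marker_raw[ok]
        if len(m) == 0:
            flags.append(False)
            continue
        upto = m[: int(np.argmax(m)) + 1]
        running = np.maximum.accumulate(upto)
        flags.append(bool(np.all(upto >= running - gradual_tol)))
    return ensemble, flags
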