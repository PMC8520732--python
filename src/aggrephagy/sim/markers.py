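"""Scripted GFP-marker recruitment traces.

Three autophagy markers with qualitatively different recruitment kinetics
at an aggregate:

* DFCP1 (omegasome) -- a transient punctum: smooth rise, plateau, fall,
  all confined to its window.
* STX17 (mature autophagosome SNARE) -- boxcar presence: sharp appearance,
  constant plateau, sharp loss around fusion/acidification.
* RAB7 (late endosome / lysosome GTPase) -- gradual, step-wise
  accumulation built from discrete contact events: many small
  kiss-and-run transfers and occasional large full-fusion steps.

All windows are half-open ``[start, end)`` frame intervals.
"""

from __future__ import annotations

import numpy as np

from .._rng import OP_MARKERS, child_rng

__all__ = ["simulate_marker_trace", "MARKER_KINDS"]

MARKER_KINDS = ("dfcp1", "stx17", "rab7")


def _dfcp1(window: tuple[int, int], n_frames: int, ramp: int) -> np.ndarray:
    start, end = window
    out = np.zeros(n_frames)
    width = end - start
    ramp = max(1, min(ramp, width // 2))
    for f in range(start, min(end, n_frames)):
        rel = f - start
        if rel < ramp:  # raised-cosine rise
            out[f] = 0.5 * (1 - np.cos(np.pi * (rel + 1) / (ramp + 1)))
        elif rel >= width - ramp:  # raised-cosine fall, zero at window close
            rem = width - rel
            out[f] = 0.5 * (1 - np.cos(np.pi * rem / (ramp + 1)))
        else:
            out[f] = 1.0
    return out


def _stx17(window: tuple[int, int], n_frames: int) -> np.ndarray:
    start, end = window
    out = np.zeros(n_frames)
    out[start : min(end, n_frames)] = 1.0
    return out


def _rab7(
    window: tuple[int, int],
    n_frames: int,
    rng: np.random.Generator,
    event_rate: float,
    kiss_gain: float,
    fusion_gain: float,
    fusion_prob: float,
) -> np.ndarray:
    start, end = window
    gains = np.zeros(n_frames)
    n_events = rng.poisson(event_rate, size=min(end, n_frames) - start)
    for i, k in enumerate(n_events):
        for _ in range(int(k)):
            is_fusion = rng.random() < fusion_prob
            gains[start + i] += fusion_gain if is_fusion else kiss_gain
    trace = np.cumsum(gains)
    trace[: start] = 0.0
    return trace


def simulate_marker_trace(
    kind: str,
    window: tuple[int, int],
    n_frames: int,
    seed: int = 0,
    *,
    dfcp1_ramp: int = 3,
    rab7_event_rate: float = 0.15,
    rab7_kiss_gain: float = 0.1,
    rab7_fusion_gain: float = 0.5,
    rab7_fusion_prob: float = 0.2,
    aggregate_id: int = 0,
) -> np.ndarray:
    """Per-frame unit-amplitude marker intensity series.

    Parameters
    ----------
    kind
        One of ``dfcp1``, ``stx17``, ``rab7``.
    window
        Half-open frame interval ``[start, end)`` of marker presence.
    n_frames
        Length of the returned series.
    seed
        Master seed; only RAB7 step placement is stochastic.
    rab7_event_rate
        Poisson rate of contact events per frame inside the window.
    rab7_kiss_gain, rab7_fusion_gain
        Intensity added per kiss-and-run / full-fusion event.
    rab7_fusion_prob
        Probability that an event is a full fusion.
    """
    start, end = window
    if not (0 <= start <= end <= n_frames):
        raise ValueError(f"window {window} outside [0, {n_frames})")
    if kind == "dfcp1":
        return _dfcp1(window, n_frames, dfcp1_ramp)
    if kind == "stx17":
        return _stx17(window, n_frames)
    if kind == "rab7":
        rng = child_rng(seed, OP_MARKERS, aggregate_id)
        return _rab7(
            window, n_frames, rng, rab7_event_rate, rab7_kiss_gain,
            rab7_fusion_gain, rab7_fusion_prob,
        )
    raise ValueError(f"unknown marker kind {kind!r}; expected one of {MARKER_KINDS}")
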