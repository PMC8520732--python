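"""Scoring pipeline output against simulator ground truth.

Greedy nearest-neighbour matching of detections to scripted positions,
detection recall/precision, centroid localization error, and track-identity
agreement.  These routines only ever see the truth tables, never the
pipeline internals, so they can arbitrate recovery claims.
"""

from __future__ import annotations

import numpy as np

from .sim.truth import GroundTruth
from .tracking import Track

__all__ = [
    "match_points",
    "detection_scores",
    "track_identity_agreement",
]


def match_points(
    candidates: np.ndarray, references: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching by ascending distance.

    Returns (candidate_index, reference_index) pairs with distance
    <= ``max_dist``.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    references = np.atleast_2d(np.asarray(references, dtype=float))
    if candidates.size == 0 or references.size == 0:
        return []
    d = np.hypot(
        candidates[:, None, 0] - references[None, :, 0],
        candidates[:, None, 1] - references[None, :, 1],
    )
    pairs = []
    used_c: set[int] = set()
    used_r: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ci, ri in order:
        if d[ci, ri] > max_dist:
            break
        if ci in used_c or ri in used_r:
            continue
        pairs.append((int(ci), int(ri)))
        used_c.add(int(ci))
        used_r.add(int(ri))
    return pairs


def detection_scores(
    det_xy: np.ndarray, true_xy: np.ndarray, max_dist: float = 2.0
) -> dict[str, float]:
    """Recall, precision, and centroid RMSE of one frame's detections."""
    pairs = match_points(det_xy, true_xy, max_dist)
    n_det = len(np.atleast_2d(det_xy)) if np.asarray(det_xy).size else 0
    n_true = len(np.atleast_2d(true_xy)) if np.asarray(true_xy).size else 0
    if pairs:
        det_xy = np.atleast_2d(det_xy)
        true_xy = np.atleast_2d(true_xy)
        errs = [
            np.hypot(*(det_xy[ci] - true_xy[ri]))
            for ci, ri in pairs
        ]
        rmse = float(np.sqrt(np.mean(np.square(errs))))
    else:
        rmse = float("nan")
    return {
        "recall": len(pairs) / n_true if n_true else float("nan"),
        "precision": len(pairs) / n_det if n_det else float("nan"),
        "rmse": rmse,
        "n_matched": float(len(pairs)),
    }


def track_identity_agreement(
    tracks: list[Track], truth: GroundTruth, max_dist: float = 3.0
) -> float:
    """Fraction of frame-to-frame links that connect detections of the
    same ground-truth aggregate.

    Each measured position is attributed to the nearest scripted aggregate
    within ``max_dist``; a link agrees when both of its endpoints belong
    to the same aggregate.
    """
    agree = total = 0
    for track in tracks:
        frames = [f for f in track.frames if f not in track.gap_frames]
        ids = {}
        for f in frames:
            x, y = track.position(f)
            ref = np.array([pos[f] for pos in truth.positions])
            d = np.hypot(ref[:, 0] - x, ref[:, 1] - y)
            ids[f] = int(np.argmin(d)) if d.min() <= max_dist else None
        for f0, f1 in zip(frames[:-1], frames[1:]):
            if f1 - f0 != 1:
                continue
            total += 1
            if ids[f0] is not None and ids[f0] == ids[f1]:
                agree += 1
    return agree / total if total else float("nan")
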