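"""pH-dependent partitioning of mKeima signal between excitation channels.

mKeima has a bimodal excitation spectrum whose balance shifts with pH:
excitation at ~445 nm dominates at cytosolic (neutral) pH and excitation at
~561 nm dominates at lysosomal (acidic) pH, while emission stays at a single
red band.  The per-particle ratio

    r = I(ex445) / (I(ex445) + I(ex561))

is therefore a pH reporter: high r = neutral, low r = acidic.  We model the
pH -> ratio mapping as a logistic (Henderson--Hasselbalch-like) transition
between two asymptotic ratios; the exact asymptotes are instrument- and
construct-dependent, so they are free parameters of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralModel",
    "ph_to_ratio",
    "simulate_acidification_trace",
    "acidification_progress",
    "frame_at_progress",
    "PH_NEUTRAL",
    "PH_ACIDIC",
]

#: Typical cytosolic and lysosomal pH used for scripted pH trajectories.
PH_NEUTRAL = 7.2
PH_ACIDIC = 4.7


@dataclass(frozen=True)
class SpectralModel:
    """Logistic pH -> mKeima-ratio mapping.

    Parameters
    ----------
    ratio_neutral
        Expected ratio at fully cytosolic pH, in (0, 1].
    ratio_acidic
        Expected ratio at fully lysosomal pH, in [0, 1).
    pka
        pH midpoint of the transition.
    hill
        Dimensionless logistic slope (>= 1 steepens the transition).
    """

    ratio_neutral: float = 0.90
    ratio_acidic: float = 0.15
    pka: float = 6.5
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio_neutral <= 1.0):
            raise ValueError(f"ratio_neutral must be in (0, 1], got {self.ratio_neutral}")
        if not (0.0 <= self.ratio_acidic < 1.0):
            raise ValueError(f"ratio_acidic must be in [0, 1), got {self.ratio_acidic}")
        if self.ratio_neutral <= self.ratio_acidic:
            raise ValueError("ratio_neutral must exceed ratio_acidic")
        if self.hill < 1.0:
            raise ValueError(f"hill must be >= 1, got {self.hill}")


def ph_to_ratio(ph, model: SpectralModel = SpectralModel()):
    """Expected mKeima ratio at a given pH.

    r(pH) = ratio_acidic + (ratio_neutral - ratio_acidic) * L(pH), with
    L the logistic 1 / (1 + exp(-hill * (pH - pKa))).  Monotone
    non-decreasing in pH; bounded by [ratio_acidic, ratio_neutral].
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH must be finite")
    with np.errstate(over="ignore"):
        logistic = 1.0 / (1.0 + np.exp(-model.hill * (ph - model.pka)))
    out = model.ratio_acidic + (model.ratio_neutral - model.ratio_acidic) * logistic
    return float(out) if out.ndim == 0 else out


def _scaled_sigmoid(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Progress curve s(t) in [0, 1]: 0 before onset, 1 after onset+duration.

    A logistic centred on onset + duration/2, rescaled so it reaches the
    endpoints exactly at the window edges (the raw logistic only reaches
    them asymptotically); clipped outside the window.  Antisymmetric about
    the midpoint, so s(onset + duration/2) = 1/2 exactly.
    """
    mid = onset + duration / 2.0
    k = 10.0 / duration  # ~99% of the transition inside the window
    lo = 1.0 / (1.0 + np.exp(k * duration / 2.0))
    hi = 1.0 - lo
    raw = 1.0 / (1.0 + np.exp(-k * (t - mid)))
    s = (raw - lo) / (hi - lo)
    return np.clip(s, 0.0, 1.0)


def simulate_acidification_trace(
    onset: int | None,
    duration: int,
    n_frames: int,
    model: SpectralModel = SpectralModel(),
) -> np.ndarray:
    """Per-frame expected ratio for one acidification event.

    The series starts at ``ratio_neutral``, descends along a sigmoid over
    ``duration`` frames beginning at ``onset``, and ends at
    ``ratio_acidic``; it crosses the half-way ratio at onset + duration/2.
    ``onset=None`` gives a constant neutral series (no event).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if onset is None:
        return np.full(n_frames, model.ratio_neutral)
    if not (0 <= onset < n_frames):
        raise ValueError(f"onset {onset} outside [0, {n_frames})")
    if duration < 1:
        raise ValueError("duration must be >= 1")
    t = np.arange(n_frames, dtype=float)
    s = _scaled_sigmoid(t, float(onset), float(duration))
    return model.ratio_neutral - (model.ratio_neutral - model.ratio_acidic) * s


def acidification_progress(onset: float, duration: float, frame) -> np.ndarray:
    """Fraction of the total ratio change completed at ``frame`` (0..1)."""
    return _scaled_sigmoid(np.asarray(frame, dtype=float), onset, duration)


def frame_at_progress(onset: float, duration: float, progress: float) -> float:
    """Continuous time at which the scripted transition reaches ``progress``.

    Inverse of :func:`acidification_progress` on (0, 1).
    """
    if not (0.0 < progress < 1.0):
        raise ValueError("progress must be in (0, 1)")
    mid = onset + duration / 2.0
    k = 10.0 / duration
    lo = 1.0 / (1.0 + np.exp(k * duration / 2.0))
    hi = 1.0 - lo
    raw = lo + progress * (hi - lo)
    return mid + np.log(raw / (1.0 - raw)) / k
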