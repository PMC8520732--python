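"""Ground-truth containers for the synthetic microscopy simulator."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motion import MotionScript

__all__ = ["AggregateScript", "GroundTruth", "SCENARIOS"]

SCENARIOS = (
    "control_1h",
    "control_8h",
    "bafilomycin",
    "sar405",
    "stalled_stx17",
    "aborted_stx17",
)


@dataclass
class AggregateScript:
    """Everything one simulated aggregate will do, decided up front.

    ``marker_windows`` maps a marker name to a list of
    ``(start, end, profile_kind)`` half-open frame windows.  ``ph_trajectory``
    is non-increasing after ``acidification_onset``.  Scripted event frames
    (``dfcp1_release_frame`` etc.) are the analysis-definition ground truth
    computed from the noiseless scripted series at construction time.
    """

    id: int
    birth_frame: int
    total_brightness: float
    radius: float
    ph_trajectory: np.ndarray
    acidification_onset: int | None
    acidification_duration: int
    marker_windows: dict[str, list[tuple[int, int, str]]]
    motion: MotionScript
    # scripted-truth event annotations (frames; None if not applicable)
    dfcp1_release_frame: int | None = None
    acid_crossing_frame: int | None = None
    half_drop_frame: int | None = None
    stx17_release_frame: int | None = None
    progress_at_stx17_release: float | None = None
    motion_switch_frame: int | None = None


@dataclass
class GroundTruth:
    """Simulator truth for one rendered field.

    ``positions[i]`` is the (n_frames, 2) xy series of aggregate ``i``;
    ``true_ratio[i]`` its noiseless expected mKeima ratio series;
    ``marker_traces[i]`` the noiseless unit-amplitude marker series per
    marker name.
    """

    scripts: list[AggregateScript]
    positions: list[np.ndarray]
    true_ratio: list[np.ndarray]
    marker_traces: list[dict[str, np.ndarray]]
    scenario: str
    n_frames: int

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario in ("bafilomycin", "sar405"):
            if any(s.acidification_onset is not None for s in self.scripts):
                raise ValueError(f"{self.scenario} scenario must contain no acidification onsets")

    def to_frame(self) -> pd.DataFrame:
        """Long-format sidecar table: one row per aggregate per frame."""
        rows = []
        for script, pos, ratio, markers in zip(
            self.scripts, self.positions, self.true_ratio, self.marker_traces
        ):
            for f in range(script.birth_frame, self.n_frames):
                active = [
                    m for m, windows in script.marker_windows.items()
                    if any(s <= f < e for s, e, _ in windows)
                ]
                rows.append({
                    "aggregate_id": script.id,
                    "frame": f,
                    "x": pos[f, 0],
                    "y": pos[f, 1],
                    "true_ratio": ratio[f],
                    "markers_active": "+".join(active),
                    "regime": script.motion.regime_per_frame[f],
                })
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
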