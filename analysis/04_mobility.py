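#!/usr/bin/env python
"""Phase-resolved aggregate mobility around the marker episode.

Simulates confined -> diffusive tracks (tether released at marker
disappearance), partitions displacements into before/during/after phases,
and estimates the switch frame by variance change-point.  Writes per-track
results and prints the phase medians.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aggrephagy.detection import ParticleDetection
from aggrephagy.events import MarkerEpisode, estimate_mobility_switch, mobility_by_phase
from aggrephagy.sim import MotionScript, simulate_positions
from aggrephagy.tracking import Track, frame_displacements

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N_TRACKS = 100
N_FRAMES, SWITCH = 80, 40
PIXEL_SIZE = 0.16  # um


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for i in range(N_TRACKS):
        ms = MotionScript.single_switch(N_FRAMES, SWITCH, 0.5, 0.5)
        pos = simulate_positions(ms, (50.0, 50.0), N_FRAMES, SEED * 3000 + i)
        track = Track(i, {
            f: ParticleDetection(frame=f, x=pos[f, 0], y=pos[f, 1], radius=4.0)
            for f in range(N_FRAMES)
        })
        episode = MarkerEpisode("stx17", 10, SWITCH - 1)
        phases = mobility_by_phase(track, episode, PIXEL_SIZE)
        est = estimate_mobility_switch(frame_displacements(track))
        rows.append({
            "track": i,
            "median_before_um": phases.median("before"),
            "median_during_um": phases.median("during"),
            "median_after_um": phases.median("after"),
            "switch_estimate": est,
            "switch_error_frames": est - SWITCH if est is not None else np.nan,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "mobility_phases.csv", index=False, float_format="%.6f")
    print(f"{N_TRACKS} tracks: median displacement per 20 s interval")
    for phase in ("before", "during", "after"):
        print(f"  {phase:7s} {df[f'median_{phase}_um'].median():.3f} um")
    print(f"switch error: median {df.switch_error_frames.median():.1f} frames, "
          f"{(df.switch_error_frames.abs() <= 2).mean():.0%} within 2 frames")


if __name__ == "__main__":
    main()
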