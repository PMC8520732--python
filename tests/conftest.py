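import numpy as np
import pytest

from aggrephagy.sim import MotionScript, NoiseModel, SpectralModel
from aggrephagy.sim.truth import AggregateScript, GroundTruth


@pytest.fixture
def legacy_spectral() -> SpectralModel:
    """Spectral model with a 0.80 neutral asymptote, used where expected
    values were derived by hand for these parameters."""
    return SpectralModel(ratio_neutral=0.80, ratio_acidic=0.15, pka=6.5, hill=1.0)


def make_static_truth(
    positions_xy,
    ratios,
    n_frames: int = 1,
    brightness: float = 2000.0,
    marker_levels=None,
    scenario: str = "control_1h",
) -> GroundTruth:
    """Hand-built ground truth: stationary aggregates at fixed ratios."""
    scripts, positions, true_ratio, marker_traces = [], [], [], []
    for i, ((x, y), r) in enumerate(zip(positions_xy, ratios)):
        motion = MotionScript.single_switch(n_frames, None)
        scripts.append(AggregateScript(
            id=i,
            birth_frame=0,
            total_brightness=brightness,
            radius=0.0,
            ph_trajectory=np.full(n_frames, 7.2),
            acidification_onset=None,
            acidification_duration=10,
            marker_windows={},
            motion=motion,
        ))
        positions.append(np.tile([x, y], (n_frames, 1)).astype(float))
        true_ratio.append(np.full(n_frames, float(r)))
        level = marker_levels[i] if marker_levels is not None else 0.0
        marker_traces.append({"stx17": np.full(n_frames, float(level))} if level else {})
    return GroundTruth(
        scripts=scripts,
        positions=positions,
        true_ratio=true_ratio,
        marker_traces=marker_traces,
        scenario=scenario,
        n_frames=n_frames,
    )
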