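"""Scenario-level simulation: whole fields of scripted aggregates.

A field is a set of aggregates, each with a scripted fate:

* ``control_1h`` / ``control_8h`` -- each aggregate acidifies with
  probability ``p_acidified`` (low at 1 h, high at 8 h after induction).
* ``bafilomycin`` / ``sar405`` -- acidification blocked (V-ATPase or
  VPS34 inhibition); no onsets at all.
* ``stalled_stx17`` -- STX17 stays on the aggregate and the ratio falls
  only partway (failed or delayed fusion).
* ``aborted_stx17`` -- the STX17 episode closes without any acidification.

The generator also records, from the noiseless scripted series, the event
frames the downstream analysis is supposed to recover (DFCP1 release,
0.8-ratio crossing, half-drop frame, STX17 release and the acidification
progress at that moment, motion switch), so recovery can be scored without
re-deriving truth from the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import OP_SCRIPTS, child_rng
from ..stack import ImageStack
from .markers import simulate_marker_trace
from .motion import MotionScript, simulate_positions
from .render import NoiseModel, render_stack
from .spectral import (
    PH_ACIDIC,
    PH_NEUTRAL,
    SpectralModel,
    frame_at_progress,
    simulate_acidification_trace,
)
from .truth import SCENARIOS, AggregateScript, GroundTruth

__all__ = ["FieldConfig", "simulate_field", "first_stays_below"]


def first_stays_below(series: np.ndarray, threshold: float) -> int | None:
    """First index at which ``series`` is below ``threshold`` and stays
    below for all remaining points; None if it never settles below."""
    below = np.asarray(series) < threshold
    if not below[-1]:
        return None
    # last index not below, +1
    not_below = np.flatnonzero(~below)
    return int(not_below[-1] + 1) if len(not_below) else 0


@dataclass(frozen=True)
class FieldConfig:
    """All knobs of one simulated field.

    Frame units throughout; ``frame_interval`` converts to seconds.
    ``markers`` selects which GFP markers are scripted and rendered (the
    live assay images one GFP fusion at a time alongside mKeima).
    """

    scenario: str = "control_8h"
    n_aggregates: int = 20
    n_frames: int = 60
    shape_yx: tuple[int, int] = (256, 256)
    p_acidified: float | None = None  # scenario default if None
    spectral: SpectralModel = field(default_factory=SpectralModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    total_brightness: float = 2000.0
    brightness_cv: float = 0.25  # lognormal spread of per-aggregate budgets
    spot_radius: float = 0.5
    psf_sigma: float = 1.0
    frame_interval: float = 20.0
    pixel_size: float = 0.16
    markers: tuple[str, ...] = ()
    marker_brightness: float = 1500.0
    # event timing (frames)
    acid_duration: int = 10
    stx17_dwell: int = 21
    stx17_release_progress: float = 0.3
    dfcp1_interval_range: tuple[int, int] = (15, 45)
    dfcp1_duration: int = 12
    stall_fraction: float = 0.5  # fraction of full ratio drop in stalled_stx17
    # motion
    diffusion_coeff: float = 0.5
    confinement_radius: float = 0.5
    min_separation: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")

    @property
    def effective_p_acidified(self) -> float:
        if self.scenario in ("bafilomycin", "sar405", "aborted_stx17"):
            return 0.0
        if self.p_acidified is not None:
            return self.p_acidified
        return {"control_1h": 0.15, "control_8h": 0.45,
                "stalled_stx17": 1.0}.get(self.scenario, 0.45)


def _cell_box(cfg: FieldConfig, margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box inside the cell footprint (with render margins):
    aggregates are placed in it and moving aggregates reflected into it,
    so spots never leave the cell or the field."""
    ny, nx = cfg.shape_yx
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax = (0.85 * 0.92 * nx / 2 - margin / 2) / np.sqrt(2.0)
    ay = (0.85 * 0.92 * ny / 2 - margin / 2) / np.sqrt(2.0)
    lo = np.array([max(margin, cx - ax), max(margin, cy - ay)])
    hi = np.array([min(nx - 1 - margin, cx + ax), min(ny - 1 - margin, cy + ay)])
    if np.any(hi <= lo):
        raise ValueError(f"field {cfg.shape_yx} too small for margin {margin}")
    return lo, hi


def _sample_positions(
    rng: np.random.Generator, cfg: FieldConfig, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Starting positions, optionally rejection-sampled for separation."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < cfg.n_aggregates:
        p = rng.uniform(lo, hi)
        if cfg.min_separation > 0 and pts:
            if np.min(np.hypot(*(np.array(pts) - p).T)) < cfg.min_separation:
                attempts += 1
                if attempts > 10000 * cfg.n_aggregates:
                    raise ValueError("cannot place aggregates at requested separation")
                continue
        pts.append(p)
    return np.array(pts)


def _reflect_box(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect a trajectory into [lo, hi] per axis (keeps render margins)."""
    span = hi - lo
    out = np.mod(pos - lo, 2 * span)
    out = np.where(out > span, 2 * span - out, out)
    return out + lo


def _script_one(
    cfg: FieldConfig, agg_id: int, start_xy: np.ndarray, seed: int
) -> tuple[AggregateScript, np.ndarray, dict[str, np.ndarray]]:
    rng = child_rng(seed, OP_SCRIPTS, agg_id)
    sp = cfg.spectral
    n = cfg.n_frames
    acidifies = rng.random() < cfg.effective_p_acidified
    brightness = cfg.total_brightness * rng.lognormal(0.0, cfg.brightness_cv)

    onset: int | None = None
    stall = cfg.scenario == "stalled_stx17"
    if acidifies and n == 1:
        # snapshot mode: acidified aggregates are imaged after completion
        onset = 0
        ratio = np.array([sp.ratio_acidic])
    elif acidifies:
        # leave room for the DFCP1 lead time before the event and for a
        # post-acidification tail after it
        lead = cfg.dfcp1_interval_range[1] + cfg.dfcp1_duration if "dfcp1" in cfg.markers else max(cfg.stx17_dwell + 2, 5)
        tail = cfg.acid_duration + 8
        onset_lo = min(lead, max(1, n - tail))
        onset_hi = max(onset_lo, n - tail)
        onset = int(rng.integers(onset_lo, onset_hi + 1))
        full = simulate_acidification_trace(onset, cfg.acid_duration, n, sp)
        if stall:
            # same kinetics, scaled to a partial drop; floor strictly above acidic
            prog = (sp.ratio_neutral - full) / (sp.ratio_neutral - sp.ratio_acidic)
            ratio = sp.ratio_neutral - cfg.stall_fraction * prog * (sp.ratio_neutral - sp.ratio_acidic)
        else:
            ratio = full
    else:
        ratio = np.full(n, sp.ratio_neutral)

    # pH trajectory consistent with the ratio progress
    prog = (sp.ratio_neutral - ratio) / (sp.ratio_neutral - sp.ratio_acidic)
    ph = PH_NEUTRAL - prog * (PH_NEUTRAL - PH_ACIDIC)

    marker_windows: dict[str, list[tuple[int, int, str]]] = {}
    traces: dict[str, np.ndarray] = {}
    acid_frame = first_stays_below(ratio, 0.8) if (acidifies and n > 1) else None
    stx17_release: int | None = None

    if "stx17" in cfg.markers:
        if acidifies and onset is not None and n > 1:
            if stall:
                w_end = n  # STX17 never leaves
            else:
                t_rel = frame_at_progress(onset, cfg.acid_duration, cfg.stx17_release_progress)
                w_end = int(round(t_rel))
            w_start = max(0, w_end - cfg.stx17_dwell)
            marker_windows["stx17"] = [(w_start, w_end, "boxcar")]
            traces["stx17"] = simulate_marker_trace("stx17", (w_start, w_end), n)
            if not stall:
                stx17_release = w_end  # first frame after presence
        elif cfg.scenario == "aborted_stx17":
            w_start = int(rng.integers(5, max(6, n - cfg.stx17_dwell - 5)))
            w_end = w_start + cfg.stx17_dwell
            marker_windows["stx17"] = [(w_start, w_end, "boxcar")]
            traces["stx17"] = simulate_marker_trace("stx17", (w_start, w_end), n)
            stx17_release = w_end

    dfcp1_release: int | None = None
    if "dfcp1" in cfg.markers and acidifies and acid_frame is not None:
        interval = int(rng.integers(cfg.dfcp1_interval_range[0], cfg.dfcp1_interval_range[1] + 1))
        target_release = acid_frame - interval
        # the raised-cosine fall crosses 0.7 two frames before the window
        # closes (ramp 3); place the window so the scripted crossing lands
        # on target_release, then re-measure truth from the actual trace
        w_end = max(cfg.dfcp1_duration, target_release + 2)
        w_start = max(0, w_end - cfg.dfcp1_duration)
        marker_windows["dfcp1"] = [(w_start, w_end, "rise_plateau_fall")]
        tr = simulate_marker_trace("dfcp1", (w_start, w_end), n)
        traces["dfcp1"] = tr
        dfcp1_release = first_stays_below(tr / tr.max(), 0.7) if tr.max() > 0 else None

    if "rab7" in cfg.markers and acidifies and onset is not None and n > 1:
        w_start = max(0, onset - 5)
        w_end = min(n, onset + cfg.acid_duration + 20)
        marker_windows["rab7"] = [(w_start, w_end, "step_accumulation")]
        traces["rab7"] = simulate_marker_trace(
            "rab7", (w_start, w_end), n, seed, aggregate_id=agg_id
        )

    # half-drop anchor from the noiseless trace
    half_drop = None
    if acidifies and n > 1:
        r_start, r_min = ratio[0], ratio.min()
        if r_start > r_min:
            half_drop = int(np.argmax(ratio <= (r_start + r_min) / 2.0))

    # motion: confined while tethered, diffusive after marker release /
    # acidification; non-acidifying aggregates stay confined
    if stx17_release is not None and cfg.scenario != "aborted_stx17":
        switch = stx17_release
    elif acid_frame is not None and n > 1:
        switch = acid_frame
    else:
        switch = None
    motion = MotionScript.single_switch(
        n, switch, cfg.diffusion_coeff, cfg.confinement_radius
    )

    progress_at_release = None
    if stx17_release is not None and acidifies and onset is not None:
        f = min(stx17_release, n - 1)
        progress_at_release = float(
            (ratio[0] - ratio[f]) / (ratio[0] - ratio.min())
        ) if ratio[0] > ratio.min() else None

    script = AggregateScript(
        id=agg_id,
        birth_frame=0,
        total_brightness=brightness,
        radius=cfg.spot_radius,
        ph_trajectory=ph,
        acidification_onset=onset,
        acidification_duration=cfg.acid_duration,
        marker_windows=marker_windows,
        motion=motion,
        dfcp1_release_frame=dfcp1_release,
        acid_crossing_frame=acid_frame,
        half_drop_frame=half_drop,
        stx17_release_frame=stx17_release,
        progress_at_stx17_release=progress_at_release,
        motion_switch_frame=switch,
    )
    return script, ratio, traces


def simulate_field(config: FieldConfig, seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """Simulate one field: scripted ground truth plus the rendered stack."""
    cfg = config
    rng = child_rng(seed, OP_SCRIPTS)
    margin = 3.0 * cfg.psf_sigma + 2.0
    lo, hi = _cell_box(cfg, margin)
    starts = _sample_positions(rng, cfg, lo, hi)

    scripts, positions, ratios, traces = [], [], [], []
    ny, nx = cfg.shape_yx
    for i in range(cfg.n_aggregates):
        script, ratio, marker_traces = _script_one(cfg, i, starts[i], seed)
        pos = simulate_positions(script.motion, tuple(starts[i]), cfg.n_frames, seed, aggregate_id=i)
        pos = _reflect_box(pos, lo, hi)
        scripts.append(script)
        positions.append(pos)
        ratios.append(ratio)
        traces.append(marker_traces)

    truth = GroundTruth(
        scripts=scripts,
        positions=positions,
        true_ratio=ratios,
        marker_traces=traces,
        scenario=cfg.scenario,
        n_frames=cfg.n_frames,
    )
    stack = render_stack(
        truth,
        cfg.noise,
        (cfg.n_frames, ny, nx),
        cfg.psf_sigma,
        seed,
        marker_brightness=cfg.marker_brightness,
        frame_interval=cfg.frame_interval,
        pixel_size=cfg.pixel_size,
    )
    return stack, truth
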