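"""Aggregate mobility: confined tether vs free diffusion.

Aggregates are largely immobile (tethered, confined) before and during the
presence of autophagosome markers and become mobile only after marker
release; the simulator encodes this as a per-frame regime sequence with a
single confined -> diffusive switch by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import OP_MOTION, child_rng

__all__ = ["MotionScript", "simulate_positions"]

CONFINED = "confined"
DIFFUSIVE = "diffusive"


@dataclass(frozen=True)
class MotionScript:
    """Per-frame motion regimes and their parameters.

    ``diffusion_coeff`` (px^2/frame) sets the Gaussian step variance
    (2*D per axis per frame) in both regimes; in the confined regime the
    walk is additionally reflected back into a disc of
    ``confinement_radius`` (px) around the anchor position.
    """

    regime_per_frame: tuple[str, ...]
    diffusion_coeff: float = 0.5
    confinement_radius: float = 0.5
    switch_frame: int | None = None

    def __post_init__(self) -> None:
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.confinement_radius < 0:
            raise ValueError("confinement_radius must be >= 0")
        bad = set(self.regime_per_frame) - {CONFINED, DIFFUSIVE}
        if bad:
            raise ValueError(f"unknown regimes: {bad}")

    @staticmethod
    def single_switch(
        n_frames: int,
        switch_frame: int | None,
        diffusion_coeff: float = 0.5,
        confinement_radius: float = 0.5,
    ) -> "MotionScript":
        """Confined up to (and excluding) ``switch_frame``, diffusive after.

        ``switch_frame=None`` means confined throughout.
        """
        if switch_frame is None:
            regimes = (CONFINED,) * n_frames
        else:
            regimes = (CONFINED,) * switch_frame + (DIFFUSIVE,) * (n_frames - switch_frame)
        return MotionScript(regimes, diffusion_coeff, confinement_radius, switch_frame)


def simulate_positions(
    motion: MotionScript,
    start_xy: tuple[float, float],
    n_frames: int,
    seed: int = 0,
    *,
    aggregate_id: int = 0,
) -> np.ndarray:
    """Simulate an (n_frames, 2) position series in pixels.

    Diffusive frames take unconstrained Gaussian steps with variance
    2*D per axis; confined frames take the same steps but are radially
    reflected into the confinement disc around the anchor (the position
    where the current confined stretch began), so no confined position
    ever lies further than the confinement radius from its anchor.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(motion.regime_per_frame) < n_frames:
        raise ValueError("regime_per_frame shorter than n_frames")
    rng = child_rng(seed, OP_MOTION, aggregate_id)
    sigma = np.sqrt(2.0 * motion.diffusion_coeff)
    steps = rng.normal(0.0, sigma, size=(n_frames, 2)) if sigma > 0 else np.zeros((n_frames, 2))

    pos = np.empty((n_frames, 2))
    pos[0] = start_xy
    anchor = np.asarray(start_xy, dtype=float)
    prev_regime = motion.regime_per_frame[0]
    for f in range(1, n_frames):
        regime = motion.regime_per_frame[f]
        if regime == CONFINED and prev_regime != CONFINED:
            anchor = pos[f - 1].copy()
        cand = pos[f - 1] + steps[f]
        if regime == CONFINED:
            cand = _reflect_into_disc(cand, anchor, motion.confinement_radius)
        pos[f] = cand
        prev_regime = regime
    return pos


def _reflect_into_disc(p: np.ndarray, centre: np.ndarray, radius: float) -> np.ndarray:
    d = p - centre
    r = float(np.hypot(*d))
    if r <= radius or r == 0.0:
        return p
    # radial reflection about the boundary; clamp if the step overshoots
    r_new = 2.0 * radius - r
    if r_new < 0.0:
        r_new = radius
    return centre + d * (r_new / r)
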