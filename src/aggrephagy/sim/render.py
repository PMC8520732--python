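"""Render ground truth into camera counts.

Each aggregate is a diffraction-limited punctum: a 2-D Gaussian whose total
photon budget per frame is split between the two mKeima excitation channels
as ratio : (1 - ratio), with the GFP marker rendered at the same centroid.
The camera model is Poisson shot noise on photons, a linear gain, and
additive Gaussian read noise (EM-register excess noise is not modelled).
Spots use the pixel-integrated Gaussian (difference of error functions), so
photon flux is conserved to the truncation of the rendering window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .._rng import OP_READ_NOISE, OP_SHOT_NOISE, child_rng
from ..stack import CHANNEL_ROLES, ImageStack
from .truth import GroundTruth

__all__ = ["NoiseModel", "render_stack", "render_zstack", "cell_mask_ellipse"]


@dataclass(frozen=True)
class NoiseModel:
    """Camera/background model.

    ``background_cell``/``background_outside`` are photons/px/frame inside
    and outside the cell footprint; ``read_noise_sd`` is in counts;
    ``gain`` in counts/photon.
    """

    background_cell: float = 20.0
    background_outside: float = 2.0
    read_noise_sd: float = 2.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if min(self.background_cell, self.background_outside, self.read_noise_sd, self.gain) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.background_cell < self.background_outside:
            raise ValueError("background_cell must be >= background_outside")

    @property
    def is_noiseless(self) -> bool:
        return self.read_noise_sd == 0 and self.background_cell == 0 and self.background_outside == 0


NOISELESS = NoiseModel(0.0, 0.0, 0.0, 1.0)


def cell_mask_ellipse(shape_yx: tuple[int, int], fill: float = 0.85) -> np.ndarray:
    """Elliptical cell footprint centred in the field."""
    ny, nx = shape_yx
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    return ((x - cx) / (fill * nx / 2)) ** 2 + ((y - cy) / (fill * ny / 2)) ** 2 <= 1.0


def _add_spot(img: np.ndarray, x: float, y: float, flux: float, sigma: float) -> None:
    """Deposit a pixel-integrated 2-D Gaussian of total ``flux`` photons."""
    if flux <= 0:
        return
    ny, nx = img.shape
    half = int(np.ceil(5 * sigma)) + 1
    x0, x1 = max(0, int(x) - half), min(nx, int(x) + half + 1)
    y0, y1 = max(0, int(y) - half), min(ny, int(y) + half + 1)
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    img[y0:y1, x0:x1] += flux * np.outer(fy, fx)


def _check_bounds(truth: GroundTruth, shape_yx: tuple[int, int], psf_sigma: float) -> None:
    ny, nx = shape_yx
    margin = 3.0 * psf_sigma
    bad = []
    for script, pos in zip(truth.scripts, truth.positions):
        p = pos[script.birth_frame:]
        if (
            p[:, 0].min() < margin or p[:, 0].max() > nx - 1 - margin
            or p[:, 1].min() < margin or p[:, 1].max() > ny - 1 - margin
        ):
            bad.append(script.id)
    if bad:
        raise ValueError(f"aggregate positions out of bounds (margin 3*psf_sigma): ids {bad}")


def render_stack(
    truth: GroundTruth,
    noise: NoiseModel,
    shape: tuple[int, int, int],
    psf_sigma: float = 1.0,
    seed: int = 0,
    *,
    marker_brightness: float = 1500.0,
    frame_interval: float = 20.0,
    pixel_size: float = 0.16,
) -> ImageStack:
    """Render a (frames, 3, y, x) time-lapse from ground truth.

    ``shape`` is (n_frames, ny, nx).  Deterministic for a given seed.
    """
    n_frames, ny, nx = shape
    _check_bounds(truth, (ny, nx), psf_sigma)
    mask = cell_mask_ellipse((ny, nx))
    bg = np.where(mask, noise.background_cell, noise.background_outside)

    photons = np.zeros((n_frames, len(CHANNEL_ROLES), ny, nx))
    photons[:, 0] += bg
    photons[:, 1] += bg
    photons[:, 2] += bg
    for script, pos, ratio, markers in zip(
        truth.scripts, truth.positions, truth.true_ratio, truth.marker_traces
    ):
        sigma = float(np.hypot(psf_sigma, script.radius)) if script.radius else psf_sigma
        for f in range(script.birth_frame, min(n_frames, len(ratio))):
            x, y = pos[f]
            b = script.total_brightness
            _add_spot(photons[f, 0], x, y, b * ratio[f], sigma)
            _add_spot(photons[f, 1], x, y, b * (1.0 - ratio[f]), sigma)
            marker_flux = sum(tr[f] for tr in markers.values()) * marker_brightness
            _add_spot(photons[f, 2], x, y, marker_flux, sigma)

    if noise.is_noiseless:
        counts = photons * noise.gain
    else:
        shot = child_rng(seed, OP_SHOT_NOISE)
        read = child_rng(seed, OP_READ_NOISE)
        counts = shot.poisson(photons).astype(float) * noise.gain
        counts += read.normal(0.0, noise.read_noise_sd, size=counts.shape)
        np.clip(counts, 0.0, None, out=counts)

    return ImageStack(
        pixels=counts,
        channel_roles=CHANNEL_ROLES,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )


def render_zstack(
    truth: GroundTruth,
    noise: NoiseModel,
    shape_yx: tuple[int, int],
    psf_sigma: float = 1.0,
    seed: int = 0,
    *,
    n_planes: int = 3,
    plane_spacing_um: float = 0.2,
    defocus_scale_um: float = 0.4,
    frame: int = 0,
    marker_brightness: float = 1500.0,
    pixel_size: float = 0.16,
) -> ImageStack:
    """Fixed-timepoint z-stack: ``n_planes`` planes, 200 nm apart by default.

    Out-of-focus planes image the same spots with an inflated lateral
    Gaussian width (flux conserved), a minimal defocus model sufficient to
    exercise average z-projection.  Returns a (Z, C, Y, X) stack with
    ``z_planes`` set.
    """
    ny, nx = shape_yx
    _check_bounds(truth, (ny, nx), psf_sigma)
    mask = cell_mask_ellipse((ny, nx))
    bg = np.where(mask, noise.background_cell, noise.background_outside)
    centre = (n_planes - 1) / 2.0

    photons = np.zeros((n_planes, len(CHANNEL_ROLES), ny, nx))
    photons += bg
    for z in range(n_planes):
        dz = (z - centre) * plane_spacing_um
        blur = np.sqrt(1.0 + (dz / defocus_scale_um) ** 2)
        for script, pos, ratio, markers in zip(
            truth.scripts, truth.positions, truth.true_ratio, truth.marker_traces
        ):
            if frame < script.birth_frame:
                continue
            sigma = float(np.hypot(psf_sigma, script.radius)) * blur
            x, y = pos[frame]
            b = script.total_brightness
            _add_spot(photons[z, 0], x, y, b * ratio[frame], sigma)
            _add_spot(photons[z, 1], x, y, b * (1.0 - ratio[frame]), sigma)
            marker_flux = sum(tr[frame] for tr in markers.values()) * marker_brightness
            _add_spot(photons[z, 2], x, y, marker_flux, sigma)

    if noise.is_noiseless:
        counts = photons * noise.gain
    else:
        shot = child_rng(seed, OP_SHOT_NOISE)
        read = child_rng(seed, OP_READ_NOISE)
        counts = shot.poisson(photons).astype(float) * noise.gain
        counts += read.normal(0.0, noise.read_noise_sd, size=counts.shape)
        np.clip(counts, 0.0, None, out=counts)

    return ImageStack(pixels=counts, z_planes=n_planes, pixel_size=pixel_size)
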