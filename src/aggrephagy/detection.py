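"""Punctum detection and per-channel intensity measurement.

The live assay detects aggregates as diffraction-limited puncta with an
approximate particle size of 4 pixels and a signal-to-noise threshold of 8,
then integrates fluorescence in the detected area in both mKeima excitation
channels.  Internals here are a standard band-pass / local-maximum / SNR
pipeline:

1. band-pass filter (difference of Gaussians) to suppress the smooth cell
   background while keeping particle-sized structure;
2. local maxima above ``snr`` times the robust noise s.d. of the filtered
   image;
3. sub-pixel centroids by intensity-weighted mean over the particle window;
4. circular-window integration minus area times the local background, which
   is the median of in-cell pixels away from every detection.

Detection runs on each mKeima channel and keeps the union of both (spots
that are fully acidified are dim under 445 nm excitation and would be
missed by a single-channel pass), merging duplicates within the minimum
separation and keeping the brighter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import closing, disk

from .stack import ImageStack

__all__ = [
    "DetectionParams",
    "ParticleDetection",
    "average_z_projection",
    "default_cell_mask",
    "detect_particles",
    "estimate_background",
    "measure_intensities",
    "detect_stack",
    "detections_to_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection parameters.

    ``particle_size`` is the approximate spot diameter in pixels;
    ``snr`` the peak-over-noise threshold; ``min_separation`` the merge
    distance (defaults to ``particle_size``); ``integration_radius`` the
    radius of the circular measurement window (defaults to
    ``particle_size``).
    """

    particle_size: float = 4.0
    snr: float = 8.0
    min_separation: float | None = None
    integration_radius: float | None = None

    def __post_init__(self) -> None:
        if self.particle_size < 1:
            raise ValueError("particle_size must be >= 1 px")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")

    @property
    def sep(self) -> float:
        return self.min_separation if self.min_separation is not None else self.particle_size

    @property
    def r_int(self) -> float:
        return self.integration_radius if self.integration_radius is not None else self.particle_size


@dataclass
class ParticleDetection:
    """One detected punctum in one frame.

    Intensities are background-subtracted integrated counts; ``flags``
    collects quality annotations (``border``, ``clamped445`` ...).
    """

    frame: int
    x: float
    y: float
    radius: float
    i445: float = np.nan
    i561: float = np.nan
    snr_observed: float = np.nan
    flags: set[str] = field(default_factory=set)


def average_z_projection(stack: ImageStack) -> ImageStack:
    """Arithmetic-mean projection of a fixed-timepoint z-stack.

    The first axis of a z-stack holds the planes; the result is a
    single-frame stack with ``z_planes`` cleared.
    """
    if stack.z_planes is None:
        raise ValueError("stack has no z dimension (z_planes is not set)")
    proj = stack.pixels.mean(axis=0, keepdims=True)
    return stack.with_pixels(proj, z_planes=None)


def default_cell_mask(stack: ImageStack, frame: int = 0) -> np.ndarray:
    """Otsu-thresholded, morphologically closed union of both mKeima
    channels; the region inside which background is measured."""
    img = stack.channel("mkeima_ex445")[frame] + stack.channel("mkeima_ex561")[frame]
    smooth = gaussian(img, sigma=4, preserve_range=True)
    if smooth.max() == smooth.min():
        return np.ones_like(img, dtype=bool)
    mask = smooth > threshold_otsu(smooth)
    mask = closing(mask, disk(5))
    # a zero-background render has no cell footprint to segment (what is
    # "outside" is vanishingly dim compared to "inside"): the whole field
    # is then equally valid for background measurement
    if not mask.all():
        inside = float(np.median(smooth[mask]))
        outside = float(np.median(smooth[~mask]))
        if outside <= 1e-3 * inside:
            return np.ones_like(img, dtype=bool)
    return mask


def _bandpass(image: np.ndarray, particle_size: float) -> np.ndarray:
    lo = gaussian(image, sigma=particle_size / 4.0, preserve_range=True)
    bg = gaussian(image, sigma=2.0 * particle_size, preserve_range=True)
    return lo - bg


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _weighted_centroid(bp: np.ndarray, py: int, px: int, w: int) -> tuple[float, float]:
    ny, nx = bp.shape
    y0, y1 = max(0, py - w), min(ny, py + w + 1)
    x0, x1 = max(0, px - w), min(nx, px + w + 1)
    win = np.clip(bp[y0:y1, x0:x1], 0.0, None)
    tot = win.sum()
    if tot <= 0:
        return float(px), float(py)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((xs * win).sum() / tot), float((ys * win).sum() / tot)


def detect_particles(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    cell_mask: np.ndarray | None = None,
    frame: int = 0,
) -> list[ParticleDetection]:
    """Detect puncta in a single channel image (positions and SNR only).

    Returns sub-pixel centroids of band-pass local maxima whose height
    exceeds ``snr`` times the robust noise s.d.; an all-constant image
    yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)) or np.any(image < 0):
        raise ValueError("image must be finite and non-negative")
    bp = _bandpass(image, params.particle_size)
    noise_region = bp[cell_mask] if cell_mask is not None else bp
    noise_sd = _robust_sd(noise_region.ravel())
    # absolute floor so a noiseless render still thresholds above numerical dust
    floor = 1e-9 * max(1.0, float(image.max()))
    thr = max(params.snr * noise_sd, floor)
    peaks = peak_local_max(
        bp, min_distance=max(1, int(round(params.sep))), threshold_abs=thr, exclude_border=False
    )
    out = []
    w = max(2, int(round(params.particle_size / 2.0)) + 1)
    for py, px in peaks:
        if cell_mask is not None and not cell_mask[py, px]:
            continue
        x, y = _weighted_centroid(bp, py, px, w)
        snr_obs = float(bp[py, px] / noise_sd) if noise_sd > 0 else float("inf")
        out.append(ParticleDetection(frame=frame, x=x, y=y, radius=params.r_int, snr_observed=snr_obs))
    return out


def _merge_detections(dets: list[ParticleDetection], sep: float) -> list[ParticleDetection]:
    """Greedy merge keeping the higher-SNR detection within ``sep``."""
    dets = sorted(dets, key=lambda d: (-d.snr_observed, d.x, d.y))
    kept: list[ParticleDetection] = []
    for d in dets:
        if all(np.hypot(d.x - k.x, d.y - k.y) >= sep for k in kept):
            kept.append(d)
    return kept


def estimate_background(
    image: np.ndarray,
    detections: list[ParticleDetection],
    cell_mask: np.ndarray,
    particle_size: float = 4.0,
) -> float:
    """Median pixel value of in-cell pixels away from every detection.

    Pixels within 2 x particle_size of any detection are excluded,
    mirroring background measurement "in regions of the cell in which no
    clusters were present".
    """
    mask = np.asarray(cell_mask, dtype=bool).copy()
    if not mask.any():
        raise ValueError("cell mask is empty; provide a larger field or mask")
    ny, nx = image.shape
    r_excl = 2.0 * particle_size
    for d in detections:
        y0, y1 = max(0, int(d.y - r_excl)), min(ny, int(d.y + r_excl) + 2)
        x0, x1 = max(0, int(d.x - r_excl)), min(nx, int(d.x + r_excl) + 2)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] &= (xs - d.x) ** 2 + (ys - d.y) ** 2 > r_excl**2
    if not mask.any():
        raise ValueError(
            "no background pixels left after excluding detections; "
            "use a larger field or a wider cell mask"
        )
    return float(np.median(image[mask]))


def _disc_window(shape: tuple[int, int], x: float, y: float, r: float):
    """Integer-pixel disc membership around (x, y); None if clipped."""
    ny, nx = shape
    x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
    y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
    clipped = x0 < 0 or y0 < 0 or x1 > nx or y1 > ny
    x0, x1 = max(0, x0), min(nx, x1)
    y0, y1 = max(0, y0), min(ny, y1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - x) ** 2 + (ys - y) ** 2 <= r**2
    return (slice(y0, y1), slice(x0, x1)), inside, clipped


def disc_sum(image: np.ndarray, x: float, y: float, r: float) -> tuple[float, int, bool]:
    """Integrated counts, pixel area, and border-clipped flag for a disc."""
    sl, inside, clipped = _disc_window(image.shape, x, y, r)
    return float(image[sl][inside].sum()), int(inside.sum()), clipped


def measure_intensities(
    ex445: np.ndarray,
    ex561: np.ndarray,
    detection: ParticleDetection,
    background445: float,
    background561: float,
) -> ParticleDetection:
    """Fill in background-subtracted integrated intensities.

    Negative background-subtracted sums clamp to zero (with a flag) so the
    ratio stays defined in [0, 1]; border-clipped windows are flagged and
    excluded from ratio statistics downstream.
    """
    s445, area, clipped445 = disc_sum(ex445, detection.x, detection.y, detection.radius)
    s561, _, clipped561 = disc_sum(ex561, detection.x, detection.y, detection.radius)
    if clipped445 or clipped561:
        detection.flags.add("border")
    i445 = s445 - area * background445
    i561 = s561 - area * background561
    if i445 < 0:
        detection.flags.add("clamped445")
        i445 = 0.0
    if i561 < 0:
        detection.flags.add("clamped561")
        i561 = 0.0
    detection.i445 = i445
    detection.i561 = i561
    return detection


def detect_stack(
    stack: ImageStack,
    params: DetectionParams = DetectionParams(),
    cell_mask: np.ndarray | None = None,
) -> list[ParticleDetection]:
    """Full per-frame detection + measurement over a time-lapse stack.

    Detects on both mKeima channels (union), estimates per-frame
    backgrounds, and measures both channels for every merged detection.
    """
    if stack.z_planes is not None:
        stack = average_z_projection(stack)
    ex445 = stack.channel("mkeima_ex445")
    ex561 = stack.channel("mkeima_ex561")
    out: list[ParticleDetection] = []
    for f in range(stack.n_frames):
        mask = cell_mask if cell_mask is not None else default_cell_mask(stack, f)
        dets = detect_particles(ex445[f], params, mask, frame=f)
        dets += detect_particles(ex561[f], params, mask, frame=f)
        dets = _merge_detections(dets, params.sep)
        bg445 = estimate_background(ex445[f], dets, mask, params.particle_size)
        bg561 = estimate_background(ex561[f], dets, mask, params.particle_size)
        for d in dets:
            measure_intensities(ex445[f], ex561[f], d, bg445, bg561)
        out.extend(dets)
    return out


def detections_to_frame(detections: list[ParticleDetection]) -> pd.DataFrame:
    """Detections as a tidy table (one row per detection)."""
    return pd.DataFrame(
        {
            "frame": [d.frame for d in detections],
            "x": [d.x for d in detections],
            "y": [d.y for d in detections],
            "radius": [d.radius for d in detections],
            "i445": [d.i445 for d in detections],
            "i561": [d.i561 for d in detections],
            "snr_observed": [min(d.snr_observed, 1e6) for d in detections],
            "flags": ["+".join(sorted(d.flags)) for d in detections],
        }
    )
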