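"""Punctum detection, background estimation, intensity measurement."""

import numpy as np
import pytest

from aggrephagy.detection import (
    DetectionParams,
    ParticleDetection,
    average_z_projection,
    detect_particles,
    detect_stack,
    detections_to_frame,
    estimate_background,
    measure_intensities,
)
from aggrephagy.sim import NOISELESS, render_stack
from aggrephagy.stack import ImageStack
from conftest import make_static_truth


def _spot_image(x, y, flux=5000.0, sigma=1.0, shape=(64, 64), bg=0.0):
    ys, xs = np.mgrid[0: shape[0], 0: shape[1]]
    g = np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma**2))
    return bg + flux * g / (2 * np.pi * sigma**2)


class TestZProjection:
    def test_single_plane_identity(self):
        px = np.random.default_rng(0).uniform(0, 10, (1, 3, 16, 16))
        stack = ImageStack(px, z_planes=1)
        assert np.array_equal(average_z_projection(stack).pixels[0], px[0])

    def test_constant_planes_average(self):
        px = np.stack([np.full((3, 8, 8), v) for v in (1.0, 2.0, 3.0)])
        stack = ImageStack(px, z_planes=3)
        assert np.allclose(average_z_projection(stack).pixels, 2.0)

    def test_random_planes_pixelwise_mean(self):
        px = np.random.default_rng(1).uniform(0, 100, (3, 3, 12, 12))
        stack = ImageStack(px, z_planes=3)
        proj = average_z_projection(stack).pixels[0]
        # exhaustive pixelwise oracle
        for c in range(3):
            for yy in range(12):
                for xx in range(12):
                    assert proj[c, yy, xx] == pytest.approx(px[:, c, yy, xx].mean())

    def test_missing_z_dimension_rejected(self):
        stack = ImageStack(np.zeros((2, 3, 8, 8)))
        with pytest.raises(ValueError):
            average_z_projection(stack)


class TestDetectParticles:
    def test_blank_image_yields_nothing(self):
        assert detect_particles(np.full((32, 32), 5.0)) == []

    def test_single_spot_localized(self):
        rng = np.random.default_rng(2)
        img = _spot_image(30.0, 40.0, flux=8000, shape=(64, 64), bg=10.0)
        img = rng.poisson(img).astype(float)
        dets = detect_particles(img)
        assert len(dets) == 1
        assert np.hypot(dets[0].x - 30.0, dets[0].y - 40.0) < 0.5

    def test_two_spots_resolved(self):
        img = _spot_image(20.0, 20.0, flux=8000) + _spot_image(30.0, 20.0, flux=8000)
        img = np.random.default_rng(3).poisson(img + 10).astype(float)
        assert len(detect_particles(img)) == 2

    def test_count_non_increasing_in_snr(self):
        rng = np.random.default_rng(4)
        img = rng.poisson(20.0, (128, 128)).astype(float)
        for x, y, flux in [(30, 30, 3000), (80, 40, 1500), (50, 90, 700), (100, 100, 300)]:
            img += _spot_image(x, y, flux=flux, shape=(128, 128))
        counts = [
            len(detect_particles(img, DetectionParams(snr=s))) for s in (2, 4, 8, 16, 50)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_rejects_invalid_image(self):
        with pytest.raises(ValueError):
            detect_particles(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestBackground:
    def test_flat_image_median(self):
        img = np.full((40, 40), 7.0)
        assert estimate_background(img, [], np.ones_like(img, bool)) == 7.0

    def test_spot_excluded_from_background(self):
        img = _spot_image(20.0, 20.0, flux=5000, shape=(64, 64), bg=3.0)
        det = ParticleDetection(frame=0, x=20.0, y=20.0, radius=4.0)
        assert estimate_background(img, [det], np.ones_like(img, bool)) == pytest.approx(3.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.ones((10, 10)), [], np.zeros((10, 10), bool))


class TestMeasureIntensities:
    def test_split_flux_recovered(self):
        truth = make_static_truth([(32.0, 32.0)], [0.8], brightness=1000.0)
        stack = render_stack(truth, NOISELESS, (1, 64, 64), seed=0)
        det = ParticleDetection(frame=0, x=32.0, y=32.0, radius=4.0)
        measure_intensities(
            stack.channel("mkeima_ex445")[0], stack.channel("mkeima_ex561")[0], det, 0.0, 0.0
        )
        assert det.i445 == pytest.approx(800.0, rel=0.01)
        assert det.i561 == pytest.approx(200.0, rel=0.01)

    def test_zero_image_zero_background(self):
        det = ParticleDetection(frame=0, x=16.0, y=16.0, radius=4.0)
        z = np.zeros((32, 32))
        measure_intensities(z, z, det, 0.0, 0.0)
        assert det.i445 == 0.0 and det.i561 == 0.0

    def test_exact_background_cancels(self):
        det = ParticleDetection(frame=0, x=16.0, y=16.0, radius=4.0)
        flat = np.full((32, 32), 9.0)
        measure_intensities(flat, flat, det, 9.0, 9.0)
        assert det.i445 == 0.0 and det.i561 == 0.0

    def test_linearity_under_scaling(self):
        truth = make_static_truth([(32.0, 32.0)], [0.6], brightness=1000.0)
        stack = render_stack(truth, NOISELESS, (1, 64, 64), seed=0)
        a445 = stack.channel("mkeima_ex445")[0]
        a561 = stack.channel("mkeima_ex561")[0]
        d1 = ParticleDetection(frame=0, x=32.0, y=32.0, radius=4.0)
        d2 = ParticleDetection(frame=0, x=32.0, y=32.0, radius=4.0)
        measure_intensities(a445, a561, d1, 0.0, 0.0)
        measure_intensities(3.0 * a445, 3.0 * a561, d2, 0.0, 0.0)
        assert d2.i445 == pytest.approx(3.0 * d1.i445, rel=1e-9)
        assert d2.i561 == pytest.approx(3.0 * d1.i561, rel=1e-9)

    def test_border_window_flagged(self):
        det = ParticleDetection(frame=0, x=1.0, y=16.0, radius=4.0)
        z = np.zeros((32, 32))
        measure_intensities(z, z, det, 0.0, 0.0)
        assert "border" in det.flags


def test_detect_stack_end_to_end_table():
    truth = make_static_truth([(20.0, 20.0), (44.0, 40.0)], [0.9, 0.1])
    stack = render_stack(truth, NOISELESS, (1, 64, 64), seed=0)
    df = detections_to_frame(detect_stack(stack))
    assert len(df) == 2
    ratios = sorted(df.i445 / (df.i445 + df.i561))
    assert ratios[0] == pytest.approx(0.1, abs=0.01)
    assert ratios[1] == pytest.approx(0.9, abs=0.01)
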