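"""LoG blob detection, the sigma-to-diameter rule and impurity filters."""

import math

import numpy as np
import pandas as pd
import pytest

from tiltgel.config import DetectionConfig, ParameterError
from tiltgel.detect import (
    detect_blobs,
    filter_particles,
    match_points,
    overlay_image,
    particle_diameter,
)
from tiltgel.project import ProjectionImage


def gaussian_scene(centers, amp=5000.0, sigma=0.5, shape=(120, 90), background=0.0):
    rr = np.arange(shape[0], dtype=float)[:, None]
    cc = np.arange(shape[1], dtype=float)[None, :]
    img = np.full(shape, background)
    for (y, x) in centers:
        img += amp * np.exp(-((rr - y) ** 2 + (cc - x) ** 2) / (2 * sigma**2))
    return ProjectionImage(pixels=img)


class TestDetectBlobs:
    def test_blank_image_yields_no_particles(self):
        out = detect_blobs(ProjectionImage(pixels=np.zeros((50, 40))), DetectionConfig())
        assert len(out) == 0
        assert list(out.columns)[:5] == ["y_px", "x_px", "sigma_px", "diameter_px",
                                         "intensity"]

    def test_single_spot_localized_within_one_pixel(self):
        scene = gaussian_scene([(60.3, 40.6)], amp=6000.0, sigma=1.0)
        out = detect_blobs(scene, DetectionConfig())
        assert len(out) == 1
        assert abs(out["y_px"].iloc[0] - 60.3) <= 1.0
        assert abs(out["x_px"].iloc[0] - 40.6) <= 1.0
        assert out["kept"].iloc[0]

    def test_fifty_separated_spots_all_found(self):
        rng = np.random.default_rng(0)
        ys = np.arange(10, 110, 10.0)
        xs = np.arange(8, 88, 16.0)
        centers = [(y + rng.uniform(-1, 1), x + rng.uniform(-1, 1))
                   for y in ys for x in xs]
        scene = gaussian_scene(centers, amp=5000.0, sigma=0.5)
        out = detect_blobs(scene, DetectionConfig())
        pairs = match_points(
            out[["y_px", "x_px"]].to_numpy(), np.array(centers), tol_px=2.0
        )
        assert len(centers) == 50
        assert len(out) == 50
        assert len(pairs) == 50

    def test_raising_threshold_never_adds_blobs(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(100, size=(150, 80)).astype(float)
        img += gaussian_scene([(40, 40), (90, 30)], amp=4000.0, sigma=0.5,
                              shape=(150, 80)).pixels
        counts = []
        for thr in (120.0, 200.0, 400.0, 900.0, 2500.0):
            cfg = DetectionConfig(log_threshold=thr)
            counts.append(len(detect_blobs(ProjectionImage(pixels=img), cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_empty_sigma_ladder_rejected(self):
        with pytest.raises(ParameterError):
            DetectionConfig(n_sigma_steps=0)


class TestParticleDiameter:
    @pytest.mark.parametrize(
        "sigma, expected",
        [
            (1.0 / math.sqrt(2.0), 2.0),
            (1.0, 2.0 * math.sqrt(2.0)),
            (0.5, math.sqrt(2.0)),
        ],
    )
    def test_diameter_rule(self, sigma, expected):
        assert particle_diameter(sigma) == pytest.approx(expected, abs=1e-12)


def particle_row(intensity, diameter):
    return {
        "y_px": 10.0, "x_px": 10.0, "sigma_px": diameter / (2 * math.sqrt(2)),
        "diameter_px": diameter, "intensity": intensity,
        "kept": True, "removal_reason": "none",
    }


class TestFilterParticles:
    @pytest.mark.parametrize(
        "intensity, diameter, kept, reason",
        [
            (16000.0, 1.9, False, "intensity"),
            (15001.0, 1.9, False, "intensity"),
            (15000.0, 2.0, True, "none"),    # strict-inequality boundary
            (1000.0, 2.5, False, "diameter"),
            (20000.0, 3.0, False, "intensity"),  # intensity checked first
        ],
    )
    def test_strict_inequality_rules(self, intensity, diameter, kept, reason):
        table = pd.DataFrame([particle_row(intensity, diameter)])
        kept_df, removed_df = filter_particles(table, DetectionConfig())
        row = (kept_df if kept else removed_df).iloc[0]
        assert bool(row["kept"]) is kept
        assert row["removal_reason"] == reason

    def test_partition_is_exact(self):
        rng = np.random.default_rng(3)
        rows = [
            particle_row(rng.uniform(0, 30000), rng.uniform(0.5, 4.0))
            for _ in range(200)
        ]
        table = pd.DataFrame(rows)
        kept, removed = filter_particles(table, DetectionConfig())
        assert len(kept) + len(removed) == len(table)
        assert kept["kept"].all()
        assert (~removed["kept"]).all()
        assert (removed["removal_reason"] != "none").all()


class TestMatchPoints:
    def test_greedy_matching_prefers_nearest(self):
        detected = np.array([[0.0, 0.0], [5.0, 5.0]])
        truth = np.array([[0.5, 0.0], [5.0, 4.5], [20.0, 20.0]])
        pairs = match_points(detected, truth, tol_px=2.0)
        assert sorted(pairs) == [(0, 0), (1, 1)]

    def test_each_point_used_once(self):
        detected = np.array([[0.0, 0.0], [1.0, 0.0]])
        truth = np.array([[0.4, 0.0]])
        pairs = match_points(detected, truth, tol_px=2.0)
        assert pairs == [(0, 0)]


class TestOverlay:
    def test_overlay_marks_particles_in_rgb(self):
        scene = gaussian_scene([(30, 30)], amp=5000.0)
        particles = detect_blobs(scene, DetectionConfig())
        rgb = overlay_image(scene, particles)
        assert rgb.dtype == np.uint8
        assert rgb.shape == scene.pixels.shape + (3,)
        # yellow circle pixels exist around the kept detection
        yellow = (rgb[..., 0] == 255) & (rgb[..., 1] == 255) & (rgb[..., 2] == 0)
        assert yellow.any()
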